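"""Poisson model of per-site supporting-read counts.

If a mate-pair library tags each true insertion site with a Poisson-distributed
number of supporting reads, the chance that a site received zero supporting
reads — and was therefore missed by the screen — is ``exp(-lambda)``, where
``lambda`` is the mean support per site.  Fitting ``lambda`` from the observed
support histogram turns catalog completeness into a single number.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class CompletenessError(ValueError):
    """Invalid input to the completeness model."""


@dataclass
class SupportHistogram:
    """Per-site supporting read counts (non-negative integers)."""

    counts: list[int]

    def __post_init__(self) -> None:
        if any((c < 0 or int(c) != c) for c in self.counts):
            raise CompletenessError("support counts must be non-negative integers")
        self.counts = [int(c) for c in self.counts]

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SupportHistogram":
        df = pd.read_csv(str(path), sep="\t")
        return cls(counts=df["support"].tolist())

    def to_tsv(self, path: str | Path, site_ids: list[str] | None = None) -> None:
        ids = site_ids or [f"site_{i}" for i in range(self.n_sites)]
        pd.DataFrame({"site": ids, "support": self.counts}).to_csv(
            str(path), sep="\t", index=False)


@dataclass
class PoissonFit:
    """Poisson fit to a support histogram.

    ``miss_prob`` is the per-site zero-count probability ``exp(-lam)``;
    ``genome_wide_miss_prob`` is the chance that at least one of ``n_sites``
    independent sites with the same mean went unsupported,
    ``1 - (1 - exp(-lam))**n_sites`` — a distinct, clearly labeled quantity.
    """

    lam: float
    n_sites: int
    miss_prob: float = field(init=False)
    genome_wide_miss_prob: float = field(init=False)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise CompletenessError("lambda must be non-negative")
        self.miss_prob = math.exp(-self.lam)
        self.genome_wide_miss_prob = 1.0 - (1.0 - self.miss_prob) ** self.n_sites


def fit_poisson(hist: SupportHistogram) -> PoissonFit:
    """Fit by the maximum-likelihood estimator: ``lambda`` = mean count."""
    if hist.n_sites < 1:
        raise CompletenessError("empty support histogram")
    return PoissonFit(lam=float(np.mean(hist.counts)), n_sites=hist.n_sites)


def miss_probability(lam: float) -> float:
    """Probability that a site has zero supporting reads: ``exp(-lambda)``."""
    if lam < 0:
        raise CompletenessError("lambda must be non-negative")
    return math.exp(-lam)


def poisson_goodness(hist: SupportHistogram, fit: PoissonFit) -> pd.DataFrame:
    """Observed vs. expected site counts per read-count bin.

    Bins run from 0 to the largest observed count; trailing bins whose
    expected count falls below 1 are aggregated into a single ``>=k`` tail bin
    (whose expected value uses the Poisson survival function), so both the
    observed and expected columns sum to ``n_sites``.
    """
    kmax = max(hist.counts)
    expected_full = fit.n_sites * stats.poisson.pmf(np.arange(kmax + 1), fit.lam)
    # tail cut: first bin from which all expected < 1 (bin 0 always kept)
    cut = kmax + 1
    while cut > 1 and expected_full[cut - 1] < 1.0:
        cut -= 1
    observed = np.bincount(hist.counts, minlength=kmax + 1)
    bins, obs_col, exp_col = [], [], []
    for k in range(cut):
        bins.append(str(k))
        obs_col.append(int(observed[k]))
        exp_col.append(float(expected_full[k]))
    tail_obs = int(observed[cut:].sum())
    tail_exp = float(fit.n_sites * stats.poisson.sf(cut - 1, fit.lam))
    bins.append(f">={cut}")
    obs_col.append(tail_obs)
    exp_col.append(tail_exp)
    return pd.DataFrame({"bin": bins, "observed": obs_col, "expected": exp_col})
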