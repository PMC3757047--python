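"""Synthetic study generator: genomes, planted Ty insertions, mate pairs, oligo tracks.

Everything downstream of this module — read classification, anchoring,
clustering, TSD calling, Poisson completeness, flanking-density analysis —
can be exercised end to end on data whose ground truth is known exactly.
The generator emulates:

* a reference genome annotated with non-overlapping protein-coding genes on
  both strands and tRNA genes in intergenic regions;
* a sample genome derived from it by planting full-length elements
  (LTR-internal-LTR, ~6 kb with ~330-bp LTRs) that duplicate a 5-bp target
  pentamer on both flanks, with insertion sites biased toward tRNA-bearing
  intergenic regions;
* an innie mate-pair library with a normal insert-size distribution
  (defaults are the 173-bp reads / 2.8-kb inserts / 16x coverage geometry of
  a 454 mate-pair library) and an optional uniform per-base error rate;
* a Spo11-oligo-like count track: Poisson background, long-tailed
  per-promoter hotspot boosts, and element-internal suppression.

Every emitter is deterministic given the seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .catalog import TeExemplar, tsd_to_insert_coords
from .detect import MatePair
from .dsb import OligoTrack


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


#: Soft target-site preference matrix (positions x ACGT).  The 5-bp
#: duplications at natural insertion sites show an A/T-rich consensus; this
#: synthetic stand-in matrix reproduces that flavor of bias so that
#: consensus-recovery code paths can be exercised against a known PWM.
DEFAULT_TSD_PWM = np.array([
    [0.30, 0.15, 0.25, 0.30],
    [0.35, 0.10, 0.10, 0.45],
    [0.35, 0.10, 0.10, 0.45],
    [0.40, 0.10, 0.10, 0.40],
    [0.35, 0.15, 0.15, 0.35],
])

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Scenario parameters; the seed fixes all randomness.

    Family proportions echo an SK1-like catalog (Ty1-dominant); the library
    geometry defaults to 173-bp reads with 2.8-kb inserts at 16x coverage;
    insertions target tRNA-adjacent intergenic regions with probability 0.9;
    oligo tracks suppress element-internal positions 15-fold.  Chromosome
    lengths and insertion count are scaled so a full scenario runs on a
    laptop; densities per kb are kept in a realistic regime.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (200_000, 200_000)
    gc_content: float = 0.38
    gene_len_mean: float = 1400.0
    intergenic_len_mean: float = 400.0
    trna_count: int = 20
    n_insertions: int = 10
    trna_bias: float = 0.9
    tsd_len: int = 5
    tsd_mode: str = "consensus"          # consensus / uniform
    family_weights: dict[str, float] = field(default_factory=lambda: {
        "Ty1": 0.72, "Ty2": 0.17, "Ty3": 0.07, "Ty5": 0.04})
    ltr_len: int = 330
    internal_len: int = 5260
    min_insertion_separation: int = 12_000
    read_len: int = 173
    insert_mean: float = 2800.0
    insert_sd: float = 280.0
    coverage: float = 16.0
    error_rate: float = 0.0
    # oligo track model
    background_rate: float = 0.01        # counts per bp
    promoter_width: int = 250
    hotspot_log_mean: float = math.log(20.0)
    hotspot_log_sd: float = 1.2          # long-tailed: flank densities span ~100-fold
    suppression_factor: float = 15.0

    def __post_init__(self) -> None:
        if not (0 <= self.trna_bias <= 1 and 0 <= self.error_rate <= 1
                and 0 < self.gc_content < 1):
            raise SimulationError("probabilities must lie in [0, 1]")
        if any(l <= 0 for l in self.chrom_lengths):
            raise SimulationError("chromosome lengths must be positive")
        if self.tsd_len != 5:
            raise SimulationError("only 5-bp target-site duplications are modeled")
        if self.read_len >= self.insert_mean:
            raise SimulationError("read length must be below the insert mean")

    @property
    def element_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named randomness stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class PlantedInsertion:
    chrom: str
    tsd_start: int           # reference coordinate of the first duplicated base
    insert_start: int
    insert_end: int
    family: str
    strand: str
    tsd: str
    trna_adjacent: bool


@dataclass
class GroundTruth:
    insertions: list[PlantedInsertion] = field(default_factory=list)
    hotspot_intensities: dict[str, float] = field(default_factory=dict)
    library: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "insertions": [asdict(i) for i in self.insertions],
                "hotspot_intensities": self.hotspot_intensities,
                "library": self.library,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            insertions=[PlantedInsertion(**i) for i in d["insertions"]],
            hotspot_intensities=d.get("hotspot_intensities", {}),
            library=d.get("library", {}))


# ---------------------------------------------------------------------------
# Reference genome and annotation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def make_reference_genome(config: SimConfig
                          ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome plus gene/tRNA annotation; deterministic given seed.

    Genes are placed non-overlapping on both strands with gamma-distributed
    lengths; tRNA genes go into randomly chosen intergenic gaps.  Returns the
    sequence dict and a GFF3-style DataFrame.
    """
    rng = config.rng(1)
    genome: dict[str, str] = {}
    rows = []
    gene_i = 0
    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        genome[chrom] = _random_dna(rng, length, config.gc_content)
        pos = 1
        gaps: list[tuple[int, int]] = []
        while True:
            gap = int(rng.exponential(config.intergenic_len_mean)) + 100
            glen = int(rng.gamma(4.0, config.gene_len_mean / 4.0))
            glen = min(max(glen, 300), 8000)
            start = pos + gap
            end = start + glen - 1
            if end + 100 > length:
                break
            gaps.append((pos, start - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_i += 1
            rows.append({"seqid": chrom, "source": "tymap_sim", "type": "gene",
                         "start": start, "end": end, "score": ".",
                         "strand": strand, "phase": ".",
                         "attributes": f"ID=gene{gene_i}"})
            pos = end + 1
        # tRNAs: share per-chromosome of the configured count, in wide gaps
        n_trna = max(1, round(config.trna_count * length
                              / sum(config.chrom_lengths)))
        wide = [g for g in gaps if g[1] - g[0] >= 250]
        if len(wide) < n_trna:
            raise SimulationError(
                f"{chrom}: gene model infeasible, only {len(wide)} gaps wide "
                f"enough for {n_trna} tRNA genes")
        for gi in rng.choice(len(wide), size=n_trna, replace=False):
            lo, hi = wide[gi]
            mid = (lo + hi) // 2
            rows.append({"seqid": chrom, "source": "tymap_sim", "type": "tRNA",
                         "start": mid - 40, "end": mid + 40, "score": ".",
                         "strand": "+" if rng.random() < 0.5 else "-",
                         "phase": ".",
                         "attributes": f"ID=trna_{chrom}_{mid}"})
    annotation = pd.DataFrame(rows).sort_values(
        ["seqid", "start"]).reset_index(drop=True)
    return genome, annotation


# ---------------------------------------------------------------------------
# Exemplars
# ---------------------------------------------------------------------------

def make_exemplars(config: SimConfig) -> list[TeExemplar]:
    """Family exemplars: LTR-internal-LTR with identical terminal repeats.

    The Ty1 LTR carries a T at the diagnostic typing position; the Ty2 LTR is
    the Ty1 LTR with that T deleted plus light divergence, so single-residue
    family typing behaves as it does on real LTR alignments.  Internal
    sequences are family-specific.
    """
    rng = config.rng(2)
    exemplars = []
    ty1_ltr = None
    for family in config.family_weights:
        if family == "Ty2" and ty1_ltr is not None:
            d = 284 - 1
            ltr = list(ty1_ltr[:d] + ty1_ltr[d + 1:])   # drop the diagnostic T
            for i in rng.choice(len(ltr), size=max(1, len(ltr) // 50),
                                replace=False):
                ltr[i] = str(rng.choice([b for b in "ACGT" if b != ltr[i]]))
            ltr = "".join(ltr)
        else:
            ltr = _random_dna(rng, config.ltr_len, config.gc_content)
            if family == "Ty1":
                ltr = ltr[:283] + "T" + ltr[284:]
                ty1_ltr = ltr
        internal = _random_dna(rng, config.internal_len, config.gc_content)
        seq = ltr + internal + ltr
        exemplars.append(TeExemplar(
            family=family, sequence=seq,
            ltr_spans=((1, len(ltr)),
                       (len(ltr) + config.internal_len + 1, len(seq))),
            internal_span=(len(ltr) + 1, len(ltr) + config.internal_len)))
    return exemplars


# ---------------------------------------------------------------------------
# Planting insertions
# ---------------------------------------------------------------------------

def _intergenic_intervals(annotation: pd.DataFrame, chrom: str,
                          length: int) -> list[tuple[int, int, bool]]:
    """(start, end, has_trna) intergenic intervals, 1-based inclusive."""
    genes = annotation[(annotation["seqid"] == chrom)
                       & (annotation["type"] == "gene")].sort_values("start")
    trnas = annotation[(annotation["seqid"] == chrom)
                       & (annotation["type"] == "tRNA")]
    bounds = [(0, 0)] + list(zip(genes["start"], genes["end"])) + \
        [(length + 1, length + 1)]
    out = []
    for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
        lo, hi = e1 + 1, s2 - 1
        if hi - lo < 200:
            continue
        has_trna = bool(((trnas["start"] >= lo) & (trnas["end"] <= hi)).any())
        out.append((lo, hi, has_trna))
    return out


def _pwm_logprob(pwm: np.ndarray, pentamer: str) -> float:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return float(sum(math.log(pwm[i, idx[b]] + 1e-9)
                     for i, b in enumerate(pentamer) if b in idx))


def plant_insertions(
    genome: dict[str, str],
    annotation: pd.DataFrame,
    exemplars: Sequence[TeExemplar],
    config: SimConfig,
) -> tuple[dict[str, str], GroundTruth]:
    """Insert full-length elements into a copy of the reference.

    Each insertion duplicates the 5-bp reference pentamer at the target site
    onto both element flanks; loci are drawn tRNA-adjacent with probability
    ``trna_bias``; in ``consensus`` mode candidate pentamers are weighted by
    the target-site preference matrix.  Raises when the requested number of
    insertions cannot be separated by ``min_insertion_separation``.
    """
    rng = config.rng(3)
    by_family = {e.family: e for e in exemplars}
    families = list(config.family_weights)
    weights = np.array([config.family_weights[f] for f in families])
    weights = weights / weights.sum()

    candidates: dict[bool, list[tuple[str, int, int]]] = {True: [], False: []}
    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        for lo, hi, has_trna in _intergenic_intervals(annotation, chrom, length):
            lo2, hi2 = lo + 50, hi - 50 - config.tsd_len
            if hi2 > lo2 and lo2 > config.insert_mean and \
                    hi2 < length - config.insert_mean:
                candidates[has_trna].append((chrom, lo2, hi2))

    chosen: list[tuple[str, int]] = []    # (chrom, tsd_start)

    def far_enough(chrom: str, pos: int) -> bool:
        return all(c != chrom or abs(p - pos) >= config.min_insertion_separation
                   for c, p in chosen)

    truth = GroundTruth()
    for _ in range(config.n_insertions):
        placed = False
        for _attempt in range(200):
            want_trna = rng.random() < config.trna_bias
            pool = candidates[want_trna] or candidates[not want_trna]
            if not pool:
                break
            chrom, lo, hi = pool[rng.integers(len(pool))]
            positions = np.arange(lo, hi + 1)
            if config.tsd_mode == "consensus":
                logw = np.array([
                    _pwm_logprob(DEFAULT_TSD_PWM,
                                 genome[chrom][p - 1:p + 4])
                    for p in positions])
                w = np.exp(logw - logw.max())
                w /= w.sum()
                tsd_start = int(rng.choice(positions, p=w))
            else:
                tsd_start = int(rng.choice(positions))
            if far_enough(chrom, tsd_start):
                family = str(rng.choice(families, p=weights))
                strand = "+" if rng.random() < 0.5 else "-"
                tsd = genome[chrom][tsd_start - 1:tsd_start + 4]
                ins_start, ins_end = tsd_to_insert_coords(tsd_start)
                truth.insertions.append(PlantedInsertion(
                    chrom=chrom, tsd_start=tsd_start,
                    insert_start=ins_start, insert_end=ins_end,
                    family=family, strand=strand, tsd=tsd,
                    trna_adjacent=want_trna))
                chosen.append((chrom, tsd_start))
                placed = True
                break
        if not placed:
            raise SimulationError(
                f"could not place {config.n_insertions} insertions with "
                f"separation {config.min_insertion_separation} bp")

    sample = dict(genome)
    for ins in sorted(truth.insertions,
                      key=lambda i: (i.chrom, -i.tsd_start)):
        elem = by_family[ins.family].sequence
        if ins.strand == "-":
            elem = revcomp(elem)
        s = sample[ins.chrom]
        t = ins.tsd_start
        # left flank ends with the pentamer; the element; pentamer again
        sample[ins.chrom] = s[:t + 4] + elem + s[t - 1:]
    return sample, truth


# ---------------------------------------------------------------------------
# Mate-pair library
# ---------------------------------------------------------------------------

def simulate_mate_pairs(sample: dict[str, str], config: SimConfig
                        ) -> list[MatePair]:
    """Innie mate pairs with normal insert sizes; uniform fragment starts.

    ``n_pairs = coverage * genome_length / (2 * read_length)``; the insert
    length is drawn normal(mean, sd) truncated below at the read length.
    A non-zero ``error_rate`` applies independent substitutions per base.
    """
    rng = config.rng(4)
    chroms = list(sample)
    lengths = np.array([len(sample[c]) for c in chroms])
    total = int(lengths.sum())
    n_pairs = int(round(config.coverage * total / (2 * config.read_len)))
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / total)
    inserts = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
    inserts = np.maximum(inserts, config.read_len).astype(int)
    starts = rng.random(n_pairs)
    pairs: list[MatePair] = []
    for i in range(n_pairs):
        chrom = chroms[chrom_idx[i]]
        clen = lengths[chrom_idx[i]]
        ins = min(int(inserts[i]), clen)
        start0 = int(starts[i] * (clen - ins + 1))
        frag = sample[chrom][start0:start0 + ins]
        r1 = frag[:config.read_len]
        r2 = revcomp(frag[-config.read_len:])
        pairs.append(MatePair(id=f"sim_{i}", read1=r1, read2=r2))
    if config.error_rate > 0:
        _apply_errors(pairs, config.error_rate, config.rng(5))
    return pairs


def _apply_errors(pairs: list[MatePair], rate: float,
                  rng: np.random.Generator) -> None:
    for p in pairs:
        for attr in ("read1", "read2"):
            seq = list(getattr(p, attr))
            hits = np.flatnonzero(rng.random(len(seq)) < rate)
            for i in hits:
                seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
            setattr(p, attr, "".join(seq))


# ---------------------------------------------------------------------------
# Oligo track
# ---------------------------------------------------------------------------

def simulate_oligo_track(
    annotation: pd.DataFrame,
    element_spans: Sequence[tuple[str, int, int]],
    config: SimConfig,
    chrom_lengths: dict[str, int] | None = None,
    promoter_intensities: dict[str, float] | None = None,
) -> tuple[OligoTrack, GroundTruth]:
    """Poisson count track: background, promoter hotspots, internal suppression.

    Counts at each position are Poisson with rate = background, multiplied by
    a per-promoter intensity (lognormal by default, or supplied explicitly by
    gene id) inside promoter windows, and divided by the suppression factor
    inside element spans.  Coordinates follow the annotation (supply the
    sample-genome annotation/spans to model elements in situ).
    """
    rng = config.rng(6)
    if chrom_lengths is None:
        chrom_lengths = {c: int(l) for c, l in
                         zip(config.chrom_names, config.chrom_lengths)}
    rates = {c: np.full(n, config.background_rate, dtype=float)
             for c, n in chrom_lengths.items()}
    truth = GroundTruth()
    genes = annotation[annotation["type"] == "gene"]
    for row in genes.itertuples(index=False):
        gene_id = row.attributes.split("ID=")[-1].split(";")[0]
        if promoter_intensities is not None:
            intensity = promoter_intensities.get(gene_id, 1.0)
        else:
            intensity = float(rng.lognormal(config.hotspot_log_mean,
                                            config.hotspot_log_sd))
        truth.hotspot_intensities[gene_id] = intensity
        if row.strand == "+":
            lo, hi = row.start - config.promoter_width, row.start - 1
        else:
            lo, hi = row.end + 1, row.end + config.promoter_width
        if row.seqid not in rates:
            continue
        n = len(rates[row.seqid])
        lo, hi = max(lo, 1), min(hi, n)
        if hi >= lo:
            rates[row.seqid][lo - 1:hi] *= intensity
    for chrom, s, e in element_spans:
        if chrom in rates:
            n = len(rates[chrom])
            rates[chrom][max(s, 1) - 1:min(e, n)] /= config.suppression_factor
    counts = {c: rng.poisson(r).astype(float) for c, r in rates.items()}
    track = OligoTrack.from_arrays(counts)
    return track, truth
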