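"""Spo11-oligo density in and around Ty insertion sites, plus burden arithmetic.

A Spo11-oligo map is a per-position count track; normalized to hits per
million mapped reads (hpM) it becomes comparable across libraries.  The module
builds analysis regions from an insertion catalog (merging closely neighboring
elements, excluding subtelomeric sites), measures windowed flanking and
element-internal densities in hpM/kb, classifies the intergenic context of
each site from the strands of the flanking genes, runs the rank-sum and ANOVA
comparisons used for the landscape statistics, and converts oligo fractions to
DSB frequencies and per-cell burdens.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._util import round_sig
from .catalog import TyCatalog, TyElement


class DsbError(ValueError):
    """Invalid input to a landscape computation."""


# ---------------------------------------------------------------------------
# Oligo track
# ---------------------------------------------------------------------------

@dataclass
class OligoTrack:
    """Per-position oligo counts by chromosome (array index 0 = position 1).

    When ``normalized`` is set, values are hpM: ``raw * 1e6 / total_mapped``,
    so the genome-wide sum is 1e6.
    """

    counts: dict[str, np.ndarray]
    total_mapped: float
    normalized: bool = False

    @classmethod
    def from_arrays(cls, counts: dict[str, np.ndarray]) -> "OligoTrack":
        arrays = {c: np.asarray(a, dtype=float) for c, a in counts.items()}
        total = float(sum(a.sum() for a in arrays.values()))
        return cls(counts=arrays, total_mapped=total, normalized=False)

    @classmethod
    def from_bedgraph(cls, path: str | Path,
                      chrom_lengths: dict[str, int]) -> "OligoTrack":
        from .io import read_bedgraph
        arrays = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
        for row in read_bedgraph(path).itertuples(index=False):
            if row.chrom not in arrays:
                raise DsbError(f"bedGraph chromosome {row.chrom!r} not in "
                               "chrom_lengths")
            arrays[row.chrom][row.start:row.end] = row.value
        total = float(sum(a.sum() for a in arrays.values()))
        return cls(counts=arrays, total_mapped=total, normalized=False)

    def to_bedgraph(self, path: str | Path) -> None:
        """Run-length-compressed bedGraph (0-based half-open)."""
        rows = []
        for chrom in self.counts:
            a = self.counts[chrom]
            if len(a) == 0:
                continue
            change = np.flatnonzero(np.diff(a)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(a)]))
            for s, e in zip(starts, ends):
                if a[s] != 0:
                    rows.append((chrom, int(s), int(e), float(a[s])))
        from .io import write_bedgraph
        write_bedgraph(path, pd.DataFrame(rows,
                       columns=["chrom", "start", "end", "value"]))

    def genome_mean_density(self) -> float:
        """Genome-average density per kb, in the track's current units."""
        total = sum(a.sum() for a in self.counts.values())
        length = sum(len(a) for a in self.counts.values())
        return 1000.0 * total / length


def normalize_to_hpm(track: OligoTrack) -> OligoTrack:
    """Scale a raw track to hits per million mapped reads; idempotent."""
    if track.normalized:
        return replace(track, counts={c: a.copy() for c, a in track.counts.items()})
    if track.total_mapped <= 0:
        raise DsbError("cannot normalize a track with total_mapped = 0")
    factor = 1e6 / track.total_mapped
    return OligoTrack(
        counts={c: a * factor for c, a in track.counts.items()},
        total_mapped=track.total_mapped,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Analysis regions
# ---------------------------------------------------------------------------

@dataclass
class AnalysisRegion:
    """A focal interval (insertion site or element span) with its members."""

    id: str
    chrom: str
    start: int
    end: int
    members: list[TyElement]


@dataclass(frozen=True)
class SubtelomereRule:
    """Exclusion of elements near chromosome ends.

    ``dist`` is the distance from a chromosome end under which an element is
    dropped.  By default only Ty5-family elements are subject to the rule:
    Ty5 integrase targets subtelomeric/silent chromatin, where meiotic DSBs
    are suppressed, whereas assembly end coordinates for other subtelomeric
    elements are too uncertain to justify dropping them.  Set
    ``families=None`` to apply the distance rule to every family, and supply
    ``chrom_lengths`` to enable right-end distances.
    """

    dist: int = 20_000
    families: frozenset[str] | None = frozenset({"Ty5"})
    chrom_lengths: dict[str, int] | None = None

    def excludes(self, element: TyElement) -> bool:
        if self.families is not None and element.family not in self.families:
            return False
        if element.insert_start - 1 < self.dist:
            return True
        if self.chrom_lengths and element.chrom in self.chrom_lengths:
            if self.chrom_lengths[element.chrom] - element.insert_end < self.dist:
                return True
        return False


def _merge_elements(elements: Sequence[TyElement], merge_dist: int,
                    prefix: str) -> list[AnalysisRegion]:
    regions: list[AnalysisRegion] = []
    by_chrom: dict[str, list[TyElement]] = {}
    for e in sorted(elements, key=lambda e: (e.chrom, e.insert_start, e.insert_end)):
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom in sorted(by_chrom):
        group: list[TyElement] = []
        end = -10**12
        for e in by_chrom[chrom]:
            if group and e.insert_start - end - 1 > merge_dist:
                regions.append(_close_region(group, prefix))
                group = []
                end = -10**12
            group.append(e)
            end = max(end, e.insert_end)
        if group:
            regions.append(_close_region(group, prefix))
    return regions


def _close_region(group: list[TyElement], prefix: str) -> AnalysisRegion:
    start = min(e.insert_start for e in group)
    end = max(e.insert_end for e in group)
    return AnalysisRegion(
        id=f"{prefix}_{group[0].chrom}_{start}",
        chrom=group[0].chrom, start=start, end=end, members=list(group))


def build_analysis_regions(
    catalog: TyCatalog | Iterable[TyElement],
    merge_dist: int = 1000,
    exclusions: SubtelomereRule | None = SubtelomereRule(),
) -> list[AnalysisRegion]:
    """Merge closely neighboring elements and apply the subtelomeric exclusion.

    Groups of elements within ``merge_dist`` of each other are treated as a
    single region; the region count is elements minus merges minus exclusions.
    """
    elements = list(catalog)
    if exclusions is not None:
        elements = [e for e in elements if not exclusions.excludes(e)]
    return _merge_elements(elements, merge_dist, "region")


def select_control_sites(
    reference_elements: TyCatalog | Iterable[TyElement],
    case_regions: Sequence[AnalysisRegion],
    min_dist: int = 2000,
    merge_dist: int = 1000,
    exclusions: SubtelomereRule | None = SubtelomereRule(),
) -> list[AnalysisRegion]:
    """Control regions: reference-genome element positions away from case sites.

    Reference elements within ``min_dist`` of any case focal interval on the
    same chromosome are removed (their landscape is not independent of the
    case insertion); survivors are merged and filtered as for cases.
    """
    cases_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in case_regions:
        cases_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    kept = []
    for e in reference_elements:
        near = False
        for cs, ce in cases_by_chrom.get(e.chrom, []):
            gap = max(cs - e.insert_end, e.insert_start - ce, 0)
            if gap < min_dist:
                near = True
                break
        if not near:
            kept.append(e)
    if exclusions is not None:
        kept = [e for e in kept if not exclusions.excludes(e)]
    return _merge_elements(kept, merge_dist, "control")


# ---------------------------------------------------------------------------
# Windowed densities
# ---------------------------------------------------------------------------

FLANK_WIDTHS = (500, 1000, 2000)


@dataclass
class FlankWindow:
    """Oligo density (hpM/kb) in a window abutting one side of a region."""

    region_id: str
    side: str                 # left / right (reference orientation)
    width: int
    density: float
    truncated: bool = False
    ltr_side: str | None = None   # "5prime" / "3prime" when orientation known


def _window_density(track: OligoTrack, chrom: str, lo: int, hi: int,
                    label: str) -> tuple[float, bool]:
    """Density over 1-based inclusive [lo, hi]; truncates at chromosome bounds."""
    if chrom not in track.counts:
        raise DsbError(f"{label}: chromosome {chrom!r} not in track")
    n = len(track.counts[chrom])
    clipped_lo, clipped_hi = max(lo, 1), min(hi, n)
    if clipped_hi < clipped_lo:
        raise DsbError(f"{label}: window [{lo}, {hi}] lies entirely outside "
                       f"chromosome {chrom} (length {n})")
    total = float(track.counts[chrom][clipped_lo - 1:clipped_hi].sum())
    width_kb = (clipped_hi - clipped_lo + 1) / 1000.0
    return total / width_kb, (clipped_lo, clipped_hi) != (lo, hi)


def flanking_density(track: OligoTrack, region: AnalysisRegion,
                     width: int, side: str) -> FlankWindow:
    """Density in a window of ``width`` bp abutting the focal interval.

    Windows abut the focal interval's edges and exclude element-internal
    sequence.  Windows truncated by a chromosome end are flagged and their
    density uses the effective window length.
    """
    if width not in FLANK_WIDTHS:
        raise DsbError(f"width must be one of {FLANK_WIDTHS}, got {width}")
    if not track.normalized:
        raise DsbError("flanking_density requires an hpM-normalized track")
    if side == "left":
        lo, hi = region.start - width, region.start - 1
    elif side == "right":
        lo, hi = region.end + 1, region.end + width
    else:
        raise DsbError(f"side must be 'left' or 'right', got {side!r}")
    density, truncated = _window_density(track, region.chrom, lo, hi, region.id)
    ltr_side = None
    strands = {m.strand for m in region.members}
    if len(strands) == 1:
        strand = strands.pop()
        # + orientation: 5' LTR faces left in reference coordinates
        ltr_side = {"left": {"+": "5prime", "-": "3prime"},
                    "right": {"+": "3prime", "-": "5prime"}}[side][strand]
    return FlankWindow(region_id=region.id, side=side, width=width,
                       density=density, truncated=truncated, ltr_side=ltr_side)


def internal_density(track: OligoTrack, chrom: str, start: int, end: int) -> float:
    """hpM/kb over an element's own span (same formula as flanking windows)."""
    if not track.normalized:
        raise DsbError("internal_density requires an hpM-normalized track")
    if end < start:
        raise DsbError(f"zero-length span ({start}, {end})")
    density, _ = _window_density(track, chrom, start, end, f"{chrom}:{start}-{end}")
    return density


def flank_report(track: OligoTrack, regions: Sequence[AnalysisRegion],
                 widths: Sequence[int] = FLANK_WIDTHS) -> pd.DataFrame:
    """Per-region, per-window density table for a set of analysis regions."""
    rows = []
    for region in regions:
        for width in widths:
            for side in ("left", "right"):
                w = flanking_density(track, region, width, side)
                rows.append({"region": region.id, "chrom": region.chrom,
                             "side": side, "ltr_side": w.ltr_side,
                             "width": width, "density": w.density,
                             "truncated": w.truncated})
    return pd.DataFrame(rows, columns=["region", "chrom", "side", "ltr_side",
                                       "width", "density", "truncated"])


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    statistic: float          # rank sum of the first sample (midranks)
    p_two_sided: float
    method: str               # "exact" / "normal"


EXACT_ENUMERATION_MAX_N = 12


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sample Wilcoxon rank-sum test with midrank ties.

    For combined n <= 12 the null distribution of the rank sum is enumerated
    exactly over all assignments of the pooled midranks; otherwise a normal
    approximation with tie correction (no continuity correction) is used.
    The two-sided p is twice the smaller tail probability, capped at 1.
    """
    a, b = [float(x) for x in a], [float(x) for x in b]
    if not a or not b:
        raise DsbError("both samples must be non-empty")
    na, nb = len(a), len(b)
    n = na + nb
    ranks = stats.rankdata(a + b)
    w = float(ranks[:na].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        sums = [sum(c) for c in itertools.combinations(ranks, na)]
        total = len(sums)
        p_le = sum(1 for s in sums if s <= w + 1e-9) / total
        p_ge = sum(1 for s in sums if s >= w - 1e-9) / total
        return RankSumResult(statistic=w,
                             p_two_sided=min(1.0, 2.0 * min(p_le, p_ge)),
                             method="exact")
    mean_w = na * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return RankSumResult(statistic=w, p_two_sided=1.0, method="normal")
    z = (w - mean_w) / math.sqrt(var_w)
    return RankSumResult(statistic=w,
                         p_two_sided=float(2.0 * stats.norm.sf(abs(z))),
                         method="normal")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA: F = MS_between / MS_within."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise DsbError("need >= 2 non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    n = sum(len(g) for g in arrays)
    k = len(arrays)
    if n <= k:
        raise DsbError("total n must exceed the number of groups")
    grand = sum(g.sum() for g in arrays) / n
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b, df_w = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w, p=0.0)
    f = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(F=float(f), df_between=df_b, df_within=df_w,
                       p=float(stats.f.sf(f, df_b, df_w)))


# ---------------------------------------------------------------------------
# Intergenic context
# ---------------------------------------------------------------------------

@dataclass
class IntergenicContext:
    region_id: str
    cls: str                  # divergent / tandem / convergent / intragenic / undetermined
    contains_trna: bool


_STRAND_CLASS = {("-", "+"): "divergent",
                 ("+", "-"): "convergent",
                 ("+", "+"): "tandem",
                 ("-", "-"): "tandem"}


def classify_intergenic(region: AnalysisRegion,
                        annotation: pd.DataFrame) -> IntergenicContext:
    """Intergenic class of a region from the strands of its flanking genes.

    Divergent regions ((-,+): two promoters face the region), tandem regions
    ((+,+) or (-,-): one promoter), and convergent regions ((+,-): no
    promoter) are distinguished solely by flanking protein-coding gene
    strands.  A focal point inside a gene is ``intragenic``; a region with no
    flanking gene on one side (chromosome end) is ``undetermined``.
    ``contains_trna`` is set when a tRNA gene lies within the intergenic
    interval.
    """
    genes = annotation[(annotation["type"] == "gene")
                       & (annotation["seqid"] == region.chrom)]
    focal = (region.start + region.end) // 2
    inside = genes[(genes["start"] <= focal) & (genes["end"] >= focal)]
    trnas = annotation[(annotation["type"] == "tRNA")
                       & (annotation["seqid"] == region.chrom)]
    if len(inside):
        return IntergenicContext(region.id, "intragenic", False)
    left = genes[genes["end"] < focal]
    right = genes[genes["start"] > focal]
    if left.empty or right.empty:
        return IntergenicContext(region.id, "undetermined", False)
    left_gene = left.loc[left["end"].idxmax()]
    right_gene = right.loc[right["start"].idxmin()]
    cls = _STRAND_CLASS[(left_gene["strand"], right_gene["strand"])]
    lo, hi = int(left_gene["end"]), int(right_gene["start"])
    has_trna = bool(((trnas["start"] >= lo) & (trnas["end"] <= hi)).any())
    return IntergenicContext(region.id, cls, has_trna)


# ---------------------------------------------------------------------------
# Burden arithmetic
# ---------------------------------------------------------------------------

@dataclass
class DsbCalibration:
    """Linear calibration from oligo measure to percent DNA broken.

    ``slope`` and ``intercept`` come from an external regression of oligo
    counts against directly measured DSB frequencies and must be supplied by
    the user (use slope 1, intercept 0 to pass through an already-calibrated
    oligo fraction).  ``efficiency`` is the relative DSB efficiency of the
    oligo-mapping strain versus wild type (default 0.8); ``chromatids_per_cell``
    and ``dsbs_per_cell`` drive the per-cell conversions.
    """

    slope: float
    intercept: float
    efficiency: float = 0.8
    chromatids_per_cell: int = 4
    dsbs_per_cell: float = 160.0

    def __post_init__(self) -> None:
        if not (0 < self.efficiency <= 1):
            raise DsbError("efficiency must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DsbCalibration":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def oligo_fraction_to_dsb_percent(oligo_fraction: float,
                                  calib: DsbCalibration) -> dict[str, float]:
    """Convert an oligo fraction (%) to percent DNA broken, 2 s.f.

    ``uncorrected = slope * oligo_fraction + intercept``;
    ``corrected = uncorrected / efficiency`` adjusts for the reduced DSB
    efficiency of the mapping strain.
    """
    uncorrected = calib.slope * oligo_fraction + calib.intercept
    corrected = uncorrected / calib.efficiency
    return {"uncorrected": round_sig(uncorrected, 2),
            "corrected": round_sig(corrected, 2)}


def burden_metrics(
    *,
    ty_genome_frac: float | None = None,
    ty_oligo_frac: float | None = None,
    orf_oligo_frac: float | None = None,
    orf_genome_frac: float | None = None,
    per_dna_frac: float | None = None,
    ty_ltr_oligo_frac: float | None = None,
    calib: DsbCalibration | None = None,
) -> dict[str, float]:
    """The printed burden conversions; all fractions are in percent.

    - ``fold_suppression`` = ty_genome_frac / ty_oligo_frac: how much colder
      Ty-internal sequence is than genome average.
    - ``orf_relative_fold`` = (orf_oligo_frac/orf_genome_frac) /
      (ty_oligo_frac/ty_genome_frac): how much colder Tys are than the
      typical open reading frame.
    - ``cell_frac`` = chromatids_per_cell * per_dna_frac: percent of meiotic
      cells with a break, assuming at most one DSB per four chromatids
      (requires per_dna_frac <= 100/chromatids).
    - ``expected_dsbs_per_cell`` = dsbs_per_cell * oligo fraction / 100 and
      its reciprocal ``one_in_n_cells`` (uses ``ty_ltr_oligo_frac`` — the
      fraction including LTR hits — when given, else ``ty_oligo_frac``).
    """
    calib = calib or DsbCalibration(slope=1.0, intercept=0.0)
    out: dict[str, float] = {}
    if ty_genome_frac is not None and ty_oligo_frac is not None:
        if ty_oligo_frac == 0:
            raise DsbError("ty_oligo_frac must be non-zero")
        out["fold_suppression"] = ty_genome_frac / ty_oligo_frac
        if orf_oligo_frac is not None and orf_genome_frac is not None:
            if orf_genome_frac == 0 or ty_genome_frac == 0:
                raise DsbError("genome fractions must be non-zero")
            out["orf_relative_fold"] = ((orf_oligo_frac / orf_genome_frac)
                                        / (ty_oligo_frac / ty_genome_frac))
    if per_dna_frac is not None:
        if per_dna_frac * calib.chromatids_per_cell > 100:
            raise DsbError(
                f"per_dna_frac {per_dna_frac} too large for "
                f"{calib.chromatids_per_cell} chromatids per cell")
        out["cell_frac"] = calib.chromatids_per_cell * per_dna_frac
    frac_for_cells = (ty_ltr_oligo_frac if ty_ltr_oligo_frac is not None
                      else ty_oligo_frac)
    if frac_for_cells is not None:
        expected = calib.dsbs_per_cell * frac_for_cells / 100.0
        out["expected_dsbs_per_cell"] = expected
        if expected > 0:
            out["one_in_n_cells"] = 1.0 / expected
    return out
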