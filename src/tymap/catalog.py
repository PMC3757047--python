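"""Ty insertion catalog: data model, TSV I/O, and summary statistics.

A catalog records where full-length Ty retrotransposons (and large fragments)
sit in a yeast genome, one row per element: chromosome, 1-based inclusive
insertion coordinates, family (Ty1..Ty5 or ambiguous), strand, whether a tRNA
gene shares the intergenic region, the 5-bp target-site duplication (TSD) if
one was observed, and completeness (full vs. fragment).

Coordinate convention: when an insertion site shows a 5-bp duplication, the
third and fourth base pairs of the duplicated pentamer are used as the start
and end coordinates of the insertion site.  :func:`tsd_to_insert_coords`
implements that rule and is the single source of truth for insertion-site
coordinates throughout the package.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from ._util import round_sig

FAMILIES = ("Ty1", "Ty2", "Ty3", "Ty4", "Ty5", "ambiguous")

#: TSD sentinel: duplication looked for but not present at the insertion site.
TSD_ABSENT = "absent"
#: TSD sentinel: presence or absence of a duplication was not determined.
TSD_UNDETERMINED = "undetermined"

#: Aligned coordinate in the Ty1 reference LTR whose T residue distinguishes
#: Ty1 (T present) from Ty2 (T absent) LTRs.
DIAGNOSTIC_LTR_POSITION = 284

_TSD_RE = re.compile(r"^[ACGT]{5}$")

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


class CatalogError(ValueError):
    """Malformed catalog record or file."""


@dataclass
class TyElement:
    """One catalog row: a Ty element anchored to reference coordinates."""

    chrom: str
    name: str
    insert_start: int
    insert_end: int
    family: str
    strand: str
    trna_adjacent: str = "unknown"  # yes / no / unknown
    tsd: str = TSD_UNDETERMINED     # 5-mer, TSD_ABSENT, or TSD_UNDETERMINED
    completeness: str = "full"      # full / fragment
    note: str = ""

    def __post_init__(self) -> None:
        if self.insert_end < self.insert_start:
            raise CatalogError(
                f"{self.name}: insert_end {self.insert_end} < insert_start "
                f"{self.insert_start}")
        if self.family not in FAMILIES:
            raise CatalogError(f"{self.name}: unknown family {self.family!r}")
        if self.strand not in ("+", "-"):
            raise CatalogError(f"{self.name}: strand must be + or -, got "
                               f"{self.strand!r}")
        if self.trna_adjacent not in ("yes", "no", "unknown"):
            raise CatalogError(f"{self.name}: bad trna_adjacent "
                               f"{self.trna_adjacent!r}")
        if self.completeness not in ("full", "fragment"):
            raise CatalogError(f"{self.name}: bad completeness "
                               f"{self.completeness!r}")
        if self.tsd not in (TSD_ABSENT, TSD_UNDETERMINED) and not _TSD_RE.match(self.tsd):
            raise CatalogError(
                f"{self.name}: TSD must be a 5-base ACGT string, "
                f"{TSD_ABSENT!r} or {TSD_UNDETERMINED!r}; got {self.tsd!r}")

    @property
    def has_tsd_sequence(self) -> bool:
        return self.tsd not in (TSD_ABSENT, TSD_UNDETERMINED)


@dataclass
class TyCatalog:
    """Ordered collection of :class:`TyElement` with unique names."""

    elements: list[TyElement] = field(default_factory=list)
    coordinate_system: str = "1-based inclusive"

    def __post_init__(self) -> None:
        names = [e.name for e in self.elements]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogError(f"duplicate element names: {dupes}")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[TyElement]:
        return iter(self.elements)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.elements])


@dataclass
class TeExemplar:
    """A full-length family exemplar sequence with its LTR/internal partition.

    ``ltr_spans`` and ``internal_span`` are 1-based inclusive intervals on
    ``sequence``.  ``diagnostic_ltr_position`` is the aligned LTR coordinate
    used for Ty1/Ty2 typing.
    """

    family: str
    sequence: str
    ltr_spans: tuple[tuple[int, int], ...]
    internal_span: tuple[int, int]
    diagnostic_ltr_position: int = DIAGNOSTIC_LTR_POSITION

    def __post_init__(self) -> None:
        lo, hi = self.internal_span
        for a, b in self.ltr_spans:
            if not (b < lo or a > hi):
                raise CatalogError(
                    f"{self.family}: internal span {self.internal_span} "
                    f"overlaps LTR span {(a, b)}")

    @property
    def internal_sequence(self) -> str:
        lo, hi = self.internal_span
        return self.sequence[lo - 1:hi]

    @property
    def ltr_sequence(self) -> str:
        a, b = self.ltr_spans[0]
        return self.sequence[a - 1:b]


@dataclass
class TsdConsensus:
    """Position-frequency matrix over the 5 TSD positions (columns A,C,G,T)."""

    matrix: np.ndarray           # shape (5, 4)
    n_observations: int

    BASES = "ACGT"

    @property
    def consensus(self) -> str:
        """Per-position majority base; ties reported as IUPAC ambiguity codes."""
        out = []
        for row in self.matrix:
            best = row.max()
            winners = frozenset(b for b, f in zip(self.BASES, row)
                                if np.isclose(f, best) and best > 0)
            out.append(_IUPAC[winners] if winners else "N")
        return "".join(out)


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["chrom", "name", "start", "end", "family", "strand",
                "trna", "tsd", "completeness", "note"]

# file tokens <-> in-memory values
_TSD_IN = {"N.D.": TSD_UNDETERMINED, "-": TSD_ABSENT}
_TSD_OUT = {TSD_UNDETERMINED: "N.D.", TSD_ABSENT: "-"}
_TRNA_IN = {"+": "yes", "-": "no", "yes": "yes", "no": "no",
            "unknown": "unknown", "?": "unknown"}


def read_catalog(path: str | Path) -> TyCatalog:
    """Read a catalog TSV (header row required); order-preserving.

    A malformed coordinate or unknown family/strand token raises
    :class:`CatalogError` naming the offending row.
    """
    df = pd.read_csv(str(path), sep="\t", dtype=str, na_filter=False)
    missing = [c for c in _TSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing columns {missing}")
    elements = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            elements.append(TyElement(
                chrom=row.chrom,
                name=row.name,
                insert_start=int(row.start),
                insert_end=int(row.end),
                family=row.family,
                strand=row.strand,
                trna_adjacent=_TRNA_IN.get(row.trna, row.trna),
                tsd=_TSD_IN.get(row.tsd, row.tsd),
                completeness=row.completeness or "full",
                note=getattr(row, "note", "") or "",
            ))
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"{path} line {i}: {exc}") from exc
    return TyCatalog(elements=elements)


def write_catalog(catalog: TyCatalog, path: str | Path) -> None:
    rows = []
    for e in catalog:
        rows.append({
            "chrom": e.chrom, "name": e.name,
            "start": e.insert_start, "end": e.insert_end,
            "family": e.family, "strand": e.strand,
            "trna": e.trna_adjacent,
            "tsd": _TSD_OUT.get(e.tsd, e.tsd),
            "completeness": e.completeness, "note": e.note,
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(str(path), sep="\t", index=False)


def load_sk1_catalog() -> TyCatalog:
    """The packaged SK1 Ty catalog (30 elements)."""
    with resources.as_file(resources.files("tymap.data") / "table1_sk1.tsv") as p:
        return read_catalog(p)


# ---------------------------------------------------------------------------
# Coordinate rule
# ---------------------------------------------------------------------------

def tsd_to_insert_coords(tsd_start: int, tsd_len: int = 5) -> tuple[int, int]:
    """Insertion-site coordinates from the first duplicated base.

    The third and fourth bases of the 5-bp duplication are the start and end
    coordinates of the insertion site: ``(tsd_start + 2, tsd_start + 3)``.
    Only ``tsd_len == 5`` is supported.
    """
    if tsd_len != 5:
        raise CatalogError(
            f"unsupported duplication length {tsd_len}; the two-coordinate "
            "convention is defined for 5-bp duplications only")
    return tsd_start + 2, tsd_start + 3


def insert_coords_to_tsd_start(insert_start: int, insert_end: int) -> int:
    """Inverse of :func:`tsd_to_insert_coords`."""
    if insert_end != insert_start + 1:
        raise CatalogError(
            f"({insert_start}, {insert_end}) is not a two-coordinate "
            "insertion site")
    return insert_start - 2


# ---------------------------------------------------------------------------
# Family typing from the diagnostic LTR residue
# ---------------------------------------------------------------------------

def _ltr_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -0.5
    return aligner


def classify_family_from_ltr(
    ltr: str,
    reference_ltr: str,
    diagnostic_position: int = DIAGNOSTIC_LTR_POSITION,
) -> str:
    """Type an LTR as Ty1 or Ty2 from the single diagnostic residue.

    The query LTR is aligned locally to the Ty1 reference LTR.  If the
    alignment covers the diagnostic reference coordinate and a T is aligned
    there, the LTR is Ty1; a gap or non-T residue at that position is Ty2; an
    alignment that does not reach the position is ``ambiguous``.
    """
    if not ltr:
        raise CatalogError("empty LTR sequence")
    if not reference_ltr or len(reference_ltr) < diagnostic_position:
        raise CatalogError("reference LTR does not contain the diagnostic position")
    aln = _ltr_aligner().align(reference_ltr, ltr.upper())[0]
    d = diagnostic_position - 1  # 0-based reference index
    ref_blocks, query_blocks = aln.aligned
    if len(ref_blocks) == 0:
        return "ambiguous"
    covered_lo = ref_blocks[0][0]
    covered_hi = ref_blocks[-1][1]
    if not (covered_lo <= d < covered_hi):
        return "ambiguous"
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        if rs <= d < re_:
            q_char = ltr.upper()[qs + (d - rs)]
            return "Ty1" if q_char == "T" else "Ty2"
    # position falls in a reference block deleted from the query
    return "Ty2"


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class CatalogSummary:
    n_total: int
    family_counts: dict[str, int]
    n_non_ty5: int
    trna_adjacent_count: int
    trna_fraction: float | None
    tsd_determined: int
    tsd_perfect: int
    tsd_perfect_fraction: float | None

    def genome_fraction(self, element_len: float, genome_len: float) -> float:
        """Percent of the genome occupied by catalog elements, 2 s.f.

        ``n_total * element_len / genome_len``, expressed in percent.
        """
        return round_sig(100.0 * self.n_total * element_len / genome_len, 2)


def catalog_summary(catalog: TyCatalog) -> CatalogSummary:
    """Family counts, tRNA adjacency, and TSD statistics for a catalog.

    The tRNA-adjacency fraction is computed over non-Ty5 elements (the Ty5
    family targets subtelomeric/silent regions, not tRNA genes); the
    perfect-duplication fraction is computed over elements whose TSD status
    was determined (sequence observed or duplication observed to be absent).
    Degenerate catalogs yield counts with the fractions set to ``None``.
    """
    counts = {f: 0 for f in FAMILIES}
    for e in catalog:
        counts[e.family] += 1
    counts = {f: n for f, n in counts.items() if n}
    non_ty5 = [e for e in catalog if e.family != "Ty5"]
    trna_count = sum(1 for e in non_ty5 if e.trna_adjacent == "yes")
    determined = [e for e in catalog if e.tsd != TSD_UNDETERMINED]
    perfect = sum(1 for e in determined if e.has_tsd_sequence)
    return CatalogSummary(
        n_total=len(catalog),
        family_counts=counts,
        n_non_ty5=len(non_ty5),
        trna_adjacent_count=trna_count,
        trna_fraction=(trna_count / len(non_ty5)) if non_ty5 else None,
        tsd_determined=len(determined),
        tsd_perfect=perfect,
        tsd_perfect_fraction=(perfect / len(determined)) if determined else None,
    )


def tsd_consensus(tsds: Sequence[str]) -> TsdConsensus:
    """Position-frequency matrix of 5-bp target-site duplications."""
    for t in tsds:
        if not _TSD_RE.match(t):
            raise CatalogError(f"TSD {t!r} is not a 5-base ACGT string")
    matrix = np.zeros((5, 4))
    for t in tsds:
        for i, b in enumerate(t):
            matrix[i, TsdConsensus.BASES.index(b)] += 1
    if tsds:
        matrix /= len(tsds)
    return TsdConsensus(matrix=matrix, n_observations=len(tsds))
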