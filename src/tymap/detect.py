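"""TE insertion discovery from mate pairs.

The strategy mirrors how dispersed repeats are found with paired-end data
when the repeat is absent from the reference assembly:

1. classify each read against a library of family exemplars, keeping only
   matches to internal (non-LTR) sequence — LTR matches are useless because
   solo LTRs and element-flanking LTRs are indistinguishable;
2. map the non-TE mate of each TE-matching pair uniquely to the reference
   (multi-mapping reads are discarded, never arbitrarily assigned);
3. cluster the resulting anchors per chromosome and pointing direction;
4. pair a rightward-pointing cluster with a converging leftward-pointing
   cluster into an insertion call, supported from both sides;
5. refine the call with junction-spanning reads, recovering the 5-bp
   target-site duplication and the element orientation.

Independently, insert-size anomalies (stretched pairs) and orphan-read
pileups flag reference-relative deletions and insertions.

The built-in mapper is an exact-seed (k=21) banded-extension unique mapper,
sufficient for the synthetic libraries this package generates; thresholds are
configurable because published pipelines rarely state theirs.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._util import revcomp
from .catalog import (TSD_ABSENT, TSD_UNDETERMINED, TeExemplar,
                      tsd_to_insert_coords)

DEFAULT_K = 21
DEFAULT_MIN_MATCH_LEN = 40
DEFAULT_MAX_MISMATCH_RATE = 0.05

#: sentinel returned by :func:`map_read_unique` for multi-mapping reads
MULTI = "multi"


class DetectError(ValueError):
    """Invalid detection configuration."""


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass
class LibraryStats:
    """Expected fragment geometry of a mate-pair library."""

    insert_mean: float
    insert_sd: float
    read_len: int = 0


@dataclass
class MatePair:
    id: str
    read1: str
    read2: str

    def __post_init__(self) -> None:
        for r in (self.read1, self.read2):
            if not r or set(r) - set("ACGTN"):
                raise DetectError(f"{self.id}: reads must be non-empty ACGTN")


@dataclass
class TeHit:
    family: str
    te_offset: int            # 1-based exemplar coordinate inside internal span
    match_len: int


@dataclass
class MappedRead:
    chrom: str
    position: int             # 1-based leftmost coordinate
    strand: str


@dataclass
class TeAnchor:
    """The genomic mate of a TE-matching pair, pointing toward the insertion."""

    chrom: str
    position: int             # proximal read edge facing the insertion
    direction: str            # points_right / points_left
    te_family: str
    te_offset: int


@dataclass
class AnchorCluster:
    chrom: str
    start: int
    end: int
    direction: str
    members: list[TeAnchor]


@dataclass
class InsertionCall:
    chrom: str
    breakpoint: tuple[int, int]
    left_support: int         # reads pointing right, from the left flank
    right_support: int        # reads pointing left, from the right flank
    family_vote: str
    orientation: str = "undetermined"   # + / - / undetermined
    tsd: str = TSD_UNDETERMINED
    status: str = "candidate"           # candidate / confirmed
    note: str = ""

    @property
    def total_support(self) -> int:
        return self.left_support + self.right_support


@dataclass
class AnomalySignal:
    chrom: str
    start: int
    end: int
    kind: str                 # deletion_in_sample / insertion_in_sample / concordant
    stretched_pairs: int = 0
    orphan_reads: int = 0
    note: str = ""


@dataclass
class MappedPairRecord:
    """Both mates of a pair after reference mapping."""

    pair_id: str
    read1: MappedRead | str | None      # MappedRead, MULTI, or None
    read2: MappedRead | str | None
    len1: int
    len2: int

    def _ok(self, m) -> bool:
        return isinstance(m, MappedRead)

    @property
    def proper(self) -> bool:
        """Both mates uniquely mapped, same chromosome, innie orientation."""
        if not (self._ok(self.read1) and self._ok(self.read2)):
            return False
        if self.read1.chrom != self.read2.chrom:
            return False
        if self.read1.strand == self.read2.strand:
            return False
        left, right = ((self.read1, self.read2)
                       if self.read1.position <= self.read2.position
                       else (self.read2, self.read1))
        return left.strand == "+" and right.strand == "-"

    @property
    def insert_size(self) -> int | None:
        if not self.proper:
            return None
        if self.read1.position <= self.read2.position:
            return self.read2.position + self.len2 - self.read1.position
        return self.read1.position + self.len1 - self.read2.position

    @property
    def orphan(self) -> MappedRead | None:
        """The uniquely mapped mate of a discordant pair, if any."""
        if self.proper:
            return None
        ok1, ok2 = self._ok(self.read1), self._ok(self.read2)
        if ok1 and not ok2:
            return self.read1
        if ok2 and not ok1:
            return self.read2
        if ok1 and ok2:       # discordant orientation or chromosome
            return self.read1
        return None


# ---------------------------------------------------------------------------
# K-mer indexes
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index over a reference genome for seed-and-verify mapping."""

    def __init__(self, genome: dict[str, str], k: int = DEFAULT_K):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i:i + k]].append((chrom, i))
        self.index = dict(self.index)

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


class TeLibraryIndex:
    """K-mer index restricted to exemplar internal (non-LTR) spans."""

    def __init__(self, exemplars: Sequence[TeExemplar], k: int = DEFAULT_K):
        if not exemplars:
            raise DetectError("exemplar library is empty")
        self.exemplars = {e.family: e for e in exemplars}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for e in exemplars:
            lo, hi = e.internal_span
            seq = e.sequence
            for i in range(lo - 1, hi - k + 1):
                self.index[seq[i:i + k]].append((e.family, i))
        self.index = dict(self.index)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


# ---------------------------------------------------------------------------
# Read classification and mapping
# ---------------------------------------------------------------------------

def classify_read(
    read: str,
    te_index: TeLibraryIndex | Sequence[TeExemplar],
    min_match_len: int = DEFAULT_MIN_MATCH_LEN,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> TeHit | None:
    """Match a read against internal (non-LTR) exemplar sequence.

    Returns the best hit when >= ``min_match_len`` bases of the read align
    within an internal span at <= ``max_mismatch_rate`` (either strand);
    LTR-only or no matches return ``None``.
    """
    if not isinstance(te_index, TeLibraryIndex):
        te_index = TeLibraryIndex(list(te_index))
    k = te_index.k
    best: TeHit | None = None
    for seq in (read, revcomp(read)):
        if len(seq) < k:
            continue
        candidates: set[tuple[str, int]] = set()
        for off in range(0, len(seq) - k + 1, k):
            for family, pos in te_index.index.get(seq[off:off + k], []):
                candidates.add((family, pos - off))
        for family, start0 in candidates:
            ex = te_index.exemplars[family]
            ex_seq = ex.sequence
            # clip the read to the exemplar bounds
            r_lo = max(0, -start0)
            r_hi = min(len(seq), len(ex_seq) - start0)
            if r_hi - r_lo < min_match_len:
                continue
            sub_read = seq[r_lo:r_hi]
            sub_ex = ex_seq[start0 + r_lo:start0 + r_hi]
            limit = int(max_mismatch_rate * len(sub_read))
            if _count_mismatches(sub_read, sub_ex, limit) > limit:
                continue
            # portion overlapping the internal span (1-based exemplar coords)
            lo, hi = ex.internal_span
            ov_lo = max(start0 + r_lo + 1, lo)
            ov_hi = min(start0 + r_hi, hi)
            internal_len = ov_hi - ov_lo + 1
            if internal_len < min_match_len:
                continue
            if best is None or internal_len > best.match_len:
                best = TeHit(family=family, te_offset=ov_lo,
                             match_len=internal_len)
    return best


def map_read_unique(
    read: str,
    genome_index: GenomeIndex,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> MappedRead | str | None:
    """Map a read to its unique best full-length location.

    Returns a :class:`MappedRead` when a single location has the best
    mismatch count within ``max_mismatch_rate``; the :data:`MULTI` sentinel
    when >= 2 equally best locations exist (discarded downstream); ``None``
    when unmapped.
    """
    k = genome_index.k
    if len(read) < k:
        return None
    limit = int(max_mismatch_rate * len(read))
    best_score = limit + 1
    best_locs: set[tuple[str, int, str]] = set()
    for strand, seq in (("+", read), ("-", revcomp(read))):
        offsets = {0, (len(seq) - k) // 2, len(seq) - k}
        candidates: set[tuple[str, int]] = set()
        for off in offsets:
            for chrom, pos in genome_index.seed_hits(seq[off:off + k]):
                candidates.add((chrom, pos - off))
        for chrom, start0 in candidates:
            if start0 < 0 or start0 + len(seq) > len(genome_index.genome[chrom]):
                continue
            target = genome_index.genome[chrom][start0:start0 + len(seq)]
            mm = _count_mismatches(seq, target, best_score)
            if mm < best_score:
                best_score = mm
                best_locs = {(chrom, start0, strand)}
            elif mm == best_score:
                best_locs.add((chrom, start0, strand))
    if best_score > limit or not best_locs:
        return None
    if len(best_locs) > 1:
        return MULTI
    chrom, start0, strand = best_locs.pop()
    return MappedRead(chrom=chrom, position=start0 + 1, strand=strand)


# ---------------------------------------------------------------------------
# Anchors and clustering
# ---------------------------------------------------------------------------

def extract_anchors(
    pairs: Iterable[MatePair],
    genome_index: GenomeIndex,
    te_index: TeLibraryIndex,
    min_match_len: int = DEFAULT_MIN_MATCH_LEN,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> tuple[list[TeAnchor], list[MatePair]]:
    """TE anchors from pairs with one TE-matching and one unique genomic mate.

    Also returns the pairs in which neither read fully resolved (candidates
    for junction-read analysis).
    """
    anchors: list[TeAnchor] = []
    leftovers: list[MatePair] = []
    for pair in pairs:
        hit1 = classify_read(pair.read1, te_index, min_match_len, max_mismatch_rate)
        hit2 = classify_read(pair.read2, te_index, min_match_len, max_mismatch_rate)
        if (hit1 is None) == (hit2 is None):
            if hit1 is None:
                leftovers.append(pair)
            continue
        te_hit = hit1 or hit2
        genomic_read = pair.read2 if hit1 else pair.read1
        mapped = map_read_unique(genomic_read, genome_index, max_mismatch_rate)
        if not isinstance(mapped, MappedRead):
            if mapped is None:
                # unmappable mate of a TE pair: junction-read candidate
                leftovers.append(pair)
            continue
        if mapped.strand == "+":
            direction = "points_right"
            position = mapped.position + len(genomic_read) - 1
        else:
            direction = "points_left"
            position = mapped.position
        anchors.append(TeAnchor(chrom=mapped.chrom, position=position,
                                direction=direction, te_family=te_hit.family,
                                te_offset=te_hit.te_offset))
    return anchors, leftovers


def cluster_anchors(anchors: Sequence[TeAnchor], max_gap: int) -> list[AnchorCluster]:
    """Single-linkage clusters per (chromosome, direction).

    Consecutive anchors <= ``max_gap`` apart join one cluster; output is
    sorted by (chromosome, start); every anchor lands in exactly one cluster;
    the result is invariant to input order.
    """
    groups: dict[tuple[str, str], list[TeAnchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.chrom, a.direction)].append(a)
    clusters: list[AnchorCluster] = []
    for (chrom, direction), members in groups.items():
        members.sort(key=lambda a: a.position)
        current: list[TeAnchor] = []
        for a in members:
            if current and a.position - current[-1].position > max_gap:
                clusters.append(AnchorCluster(
                    chrom=chrom, start=current[0].position,
                    end=current[-1].position, direction=direction,
                    members=current))
                current = []
            current.append(a)
        if current:
            clusters.append(AnchorCluster(
                chrom=chrom, start=current[0].position,
                end=current[-1].position, direction=direction,
                members=current))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.direction))
    return clusters


def _majority_family(members: Sequence[TeAnchor]) -> str:
    votes = Counter(a.te_family for a in members)
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "ambiguous"
    return top[0][0]


def call_insertions(
    clusters: Sequence[AnchorCluster],
    pairing_window: int,
    min_support: int = 2,
    overlap_slack: int = 200,
) -> list[InsertionCall]:
    """Pair converging clusters into insertion calls.

    A rightward-pointing cluster and a downstream leftward-pointing cluster
    whose facing edges converge within ``pairing_window`` yield one call with
    the breakpoint between them; ``confirmed`` requires support from both
    directions and total support >= ``min_support``.  Unpaired clusters emit
    candidate calls.  The family vote is the majority family of all members
    (ambiguous on a tie).
    """
    by_chrom: dict[str, dict[str, list[AnchorCluster]]] = defaultdict(
        lambda: {"points_right": [], "points_left": []})
    for c in clusters:
        by_chrom[c.chrom][c.direction].append(c)
    calls: list[InsertionCall] = []
    for chrom in sorted(by_chrom):
        rights = sorted(by_chrom[chrom]["points_right"], key=lambda c: c.end)
        lefts = sorted(by_chrom[chrom]["points_left"], key=lambda c: c.start)
        used_left: set[int] = set()
        for rc in rights:
            best_j, best_gap = None, None
            for j, lc in enumerate(lefts):
                if j in used_left:
                    continue
                gap = lc.start - rc.end
                if -overlap_slack <= gap <= pairing_window:
                    if best_gap is None or abs(gap) < abs(best_gap):
                        best_j, best_gap = j, gap
            if best_j is None:
                calls.append(InsertionCall(
                    chrom=chrom, breakpoint=(rc.end, rc.end),
                    left_support=len(rc.members), right_support=0,
                    family_vote=_majority_family(rc.members),
                    status="candidate"))
                continue
            used_left.add(best_j)
            lc = lefts[best_j]
            members = rc.members + lc.members
            bp = (min(rc.end, lc.start), max(rc.end, lc.start))
            n_left, n_right = len(rc.members), len(lc.members)
            status = ("confirmed"
                      if n_left >= 1 and n_right >= 1
                      and n_left + n_right >= min_support else "candidate")
            calls.append(InsertionCall(
                chrom=chrom, breakpoint=bp,
                left_support=n_left, right_support=n_right,
                family_vote=_majority_family(members), status=status))
        for j, lc in enumerate(lefts):
            if j not in used_left:
                calls.append(InsertionCall(
                    chrom=chrom, breakpoint=(lc.start, lc.start),
                    left_support=0, right_support=len(lc.members),
                    family_vote=_majority_family(lc.members),
                    status="candidate"))
    calls.sort(key=lambda c: (c.chrom, c.breakpoint))
    return calls


# ---------------------------------------------------------------------------
# Structural anomalies
# ---------------------------------------------------------------------------

def map_pairs(pairs: Iterable[MatePair], genome_index: GenomeIndex,
              max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
              ) -> list[MappedPairRecord]:
    out = []
    for p in pairs:
        out.append(MappedPairRecord(
            pair_id=p.id,
            read1=map_read_unique(p.read1, genome_index, max_mismatch_rate),
            read2=map_read_unique(p.read2, genome_index, max_mismatch_rate),
            len1=len(p.read1), len2=len(p.read2)))
    return out


def _cluster_intervals(items: list[tuple[int, int]], gap: int
                       ) -> list[tuple[int, int, int]]:
    """Merge (start, end) intervals closer than ``gap``; returns (start, end, n)."""
    items = sorted(items)
    merged: list[list[int]] = []
    for s, e in items:
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] += 1
        else:
            merged.append([s, e, 1])
    return [(s, e, n) for s, e, n in merged]


def detect_structural_anomalies(
    mapped_pairs: Sequence[MappedPairRecord],
    library_stats: LibraryStats,
    z_threshold: float = 3.0,
    min_region_pairs: int = 2,
) -> list[AnomalySignal]:
    """Flag reference-relative structural differences from pair geometry.

    Pairs whose insert exceeds mean + z*sd span sequence present in the
    reference but absent from the sample (``deletion_in_sample``); pileups of
    orphan reads — one mate unmapped or discordantly mapped — mark sample
    sequence absent from the reference (``insertion_in_sample``).
    Chromosomes with no anomalies yield a single ``concordant`` signal;
    clusters below ``min_region_pairs`` are reported concordant with a
    low-coverage note.
    """
    threshold = library_stats.insert_mean + z_threshold * library_stats.insert_sd
    stretched: dict[str, list[tuple[int, int]]] = defaultdict(list)
    orphans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    chroms: set[str] = set()
    spans: dict[str, int] = defaultdict(int)
    for rec in mapped_pairs:
        for m, ln in ((rec.read1, rec.len1), (rec.read2, rec.len2)):
            if isinstance(m, MappedRead):
                chroms.add(m.chrom)
                spans[m.chrom] = max(spans[m.chrom], m.position + ln - 1)
        ins = rec.insert_size
        if ins is not None and ins > threshold:
            left, right = ((rec.read1, rec.read2)
                           if rec.read1.position <= rec.read2.position
                           else (rec.read2, rec.read1))
            left_len = rec.len1 if left is rec.read1 else rec.len2
            stretched[left.chrom].append(
                (left.position + left_len, right.position - 1))
        orphan = rec.orphan
        if orphan is not None:
            orphans[orphan.chrom].append((orphan.position, orphan.position))
    signals: list[AnomalySignal] = []
    gap = int(library_stats.insert_mean)
    flagged: set[str] = set()
    for chrom, intervals in stretched.items():
        for s, e, n in _cluster_intervals(intervals, gap):
            if n >= min_region_pairs:
                signals.append(AnomalySignal(chrom, s, e, "deletion_in_sample",
                                             stretched_pairs=n))
                flagged.add(chrom)
            else:
                signals.append(AnomalySignal(chrom, s, e, "concordant",
                                             note="low coverage: "
                                             f"{n} stretched pair(s)"))
    for chrom, points in orphans.items():
        for s, e, n in _cluster_intervals(points, gap):
            if n >= min_region_pairs:
                signals.append(AnomalySignal(chrom, s, e, "insertion_in_sample",
                                             orphan_reads=n))
                flagged.add(chrom)
            else:
                signals.append(AnomalySignal(chrom, s, e, "concordant",
                                             note=f"low coverage: {n} orphan(s)"))
    for chrom in sorted(chroms - flagged):
        if not any(s.chrom == chrom and s.kind == "concordant" for s in signals):
            signals.append(AnomalySignal(chrom, 1, spans[chrom], "concordant"))
    signals.sort(key=lambda s: (s.chrom, s.start))
    return signals


# ---------------------------------------------------------------------------
# TSD and orientation from junction reads
# ---------------------------------------------------------------------------

@dataclass
class _JunctionObs:
    side: str                 # left / right
    genome_edge: int          # 1-based: last ref base before / first after element
    orientation: str          # + / -


def _genome_prefix_extent(seq: str, genome: str, start0: int) -> int:
    """Length of the exact match of ``seq`` against genome from ``start0``."""
    n = 0
    for i, ch in enumerate(seq):
        j = start0 + i
        if j >= len(genome) or genome[j] != ch:
            break
        n += 1
    return n


def _genome_suffix_extent(seq: str, genome: str, end0: int) -> int:
    """Length of the exact match of ``seq`` ending at genome index ``end0``."""
    n = 0
    for i in range(len(seq) - 1, -1, -1):
        j = end0 - (len(seq) - 1 - i)
        if j < 0 or genome[j] != seq[i]:
            break
        n += 1
    return n


def _element_terminus_match(seq: str, exemplars: Sequence[TeExemplar],
                            end: str) -> str | None:
    """Orientation if ``seq`` matches an element terminus, else None.

    ``end='start'``: seq should be the first bases of the inserted element
    (right of a left junction); ``end='end'``: the last bases (left of a
    right junction).  Both element orientations are checked.
    """
    if len(seq) < 5:
        return None
    for ex in exemplars:
        for orientation, elem in (("+", ex.sequence), ("-", revcomp(ex.sequence))):
            if end == "start" and elem.startswith(seq):
                return orientation
            if end == "end" and elem.endswith(seq):
                return orientation
    return None


def find_junction_observations(
    read: str,
    genome: dict[str, str],
    genome_index: GenomeIndex,
    chrom: str,
    approx_breakpoint: int,
    exemplars: Sequence[TeExemplar],
    window: int = 1000,
    min_flank: int = 10,
) -> list[_JunctionObs]:
    """Split a read at an element-genome junction near a breakpoint.

    A left-junction read carries genomic sequence then element sequence; a
    right-junction read the reverse.  Exact extension from a seeded anchor
    locates the genomic edge; the non-genomic part must match an element
    terminus in either orientation.
    """
    k = genome_index.k
    obs: list[_JunctionObs] = []
    seq_g = genome[chrom]
    for seq in (read, revcomp(read)):
        if len(seq) < k:
            continue
        # genomic prefix -> left junction.  The maximal genomic extension can
        # overrun the true junction when reference sequence past the target
        # site coincidentally matches the element start, so the split point
        # is backed off until the remainder matches an element terminus.
        for hit_chrom, pos0 in genome_index.seed_hits(seq[:k]):
            if hit_chrom != chrom or abs(pos0 + 1 - approx_breakpoint) > window:
                continue
            ext = _genome_prefix_extent(seq, seq_g, pos0)
            for trim in range(0, min(ext - min_flank, 12) + 1):
                rest = seq[ext - trim:]
                if len(rest) < min_flank:
                    continue
                orientation = _element_terminus_match(rest, exemplars, "start")
                if orientation is not None:
                    obs.append(_JunctionObs("left", pos0 + ext - trim,
                                            orientation))
                    break
        # genomic suffix -> right junction (mirror logic)
        for hit_chrom, pos0 in genome_index.seed_hits(seq[-k:]):
            end0 = pos0 + k - 1
            if hit_chrom != chrom or abs(end0 + 1 - approx_breakpoint) > window + len(seq):
                continue
            ext = _genome_suffix_extent(seq, seq_g, end0)
            for trim in range(0, min(ext - min_flank, 12) + 1):
                rest = seq[:len(seq) - ext + trim]
                if len(rest) < min_flank:
                    continue
                orientation = _element_terminus_match(rest, exemplars, "end")
                if orientation is not None:
                    start1 = end0 - ext + trim + 2  # 1-based first genomic base
                    obs.append(_JunctionObs("right", start1, orientation))
                    break
    return obs


def _mode(values: list[int]) -> int:
    return Counter(values).most_common(1)[0][0]


def call_tsd_and_orientation(
    call: InsertionCall,
    junction_reads: Sequence[str],
    genome: dict[str, str],
    exemplars: Sequence[TeExemplar],
    genome_index: GenomeIndex | None = None,
    window: int = 1000,
) -> InsertionCall:
    """Refine a call with junction-spanning reads.

    When both junctions resolve and the genomic edges overlap by exactly 5
    bases, that pentamer is the target-site duplication and the breakpoint
    collapses to the two-coordinate convention.  Edges that abut without
    overlap mean no duplication (``tsd = absent``); anything else, or
    contradictory reads, leaves the TSD undetermined.  Orientation comes from
    which exemplar end abuts each junction.
    """
    if genome_index is None:
        genome_index = GenomeIndex(genome)
    approx = (call.breakpoint[0] + call.breakpoint[1]) // 2
    obs: list[_JunctionObs] = []
    for read in junction_reads:
        obs.extend(find_junction_observations(
            read, genome, genome_index, call.chrom, approx, exemplars,
            window=window))
    lefts = [o for o in obs if o.side == "left"]
    rights = [o for o in obs if o.side == "right"]
    if not obs:
        return call
    orientations = {o.orientation for o in obs}
    if len(orientations) == 1:
        call.orientation = orientations.pop()
    else:
        call.orientation = "undetermined"
        call.note = (call.note + "; " if call.note else "") + \
            "conflicting junction orientations"
    if not lefts or not rights:
        return call
    left_edge = _mode([o.genome_edge for o in lefts])    # last ref base before element
    right_edge = _mode([o.genome_edge for o in rights])  # first ref base after element
    overlap = left_edge - right_edge + 1
    if overlap == 5:
        tsd_start = right_edge
        seq = genome[call.chrom][tsd_start - 1:tsd_start + 4]
        call.tsd = seq
        call.breakpoint = tsd_to_insert_coords(tsd_start)
    elif overlap == 0:
        call.tsd = TSD_ABSENT
        call.breakpoint = (left_edge, right_edge)
    else:
        call.tsd = TSD_UNDETERMINED
        call.note = (call.note + "; " if call.note else "") + \
            f"junction edges overlap by {overlap} bases"
    return call


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class DetectionResult:
    calls: list[InsertionCall]
    anomalies: list[AnomalySignal]
    support_counts: list[int] = field(default_factory=list)


def detect_insertions(
    pairs: Sequence[MatePair],
    genome: dict[str, str],
    exemplars: Sequence[TeExemplar],
    library_stats: LibraryStats,
    max_gap: int | None = None,
    pairing_window: int | None = None,
    min_support: int = 2,
    min_match_len: int = DEFAULT_MIN_MATCH_LEN,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    with_anomalies: bool = False,
) -> DetectionResult:
    """Full detection pipeline on a mate-pair library.

    ``max_gap`` and ``pairing_window`` default to the library's expected
    insert size, since anchor spread is bounded by the insert length.
    """
    if max_gap is None:
        max_gap = int(library_stats.insert_mean)
    if pairing_window is None:
        pairing_window = int(library_stats.insert_mean)
    genome_index = GenomeIndex(genome)
    te_index = TeLibraryIndex(list(exemplars))
    anchors, leftovers = extract_anchors(
        pairs, genome_index, te_index, min_match_len, max_mismatch_rate)
    clusters = cluster_anchors(anchors, max_gap)
    calls = call_insertions(clusters, pairing_window, min_support)
    # junction refinement: reads that resolved neither as TE nor as genomic
    junction_pool: list[str] = []
    for p in leftovers:
        for r in (p.read1, p.read2):
            if map_read_unique(r, genome_index, max_mismatch_rate) is None:
                junction_pool.append(r)
    for call in calls:
        call_tsd_and_orientation(call, junction_pool, genome, exemplars,
                                 genome_index=genome_index)
    anomalies: list[AnomalySignal] = []
    if with_anomalies:
        mapped = map_pairs(pairs, genome_index, max_mismatch_rate)
        anomalies = detect_structural_anomalies(mapped, library_stats)
    support = [c.total_support for c in calls if c.status == "confirmed"]
    return DetectionResult(calls=calls, anomalies=anomalies,
                           support_counts=support)
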