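"""Seed-and-extend mapping of bisulfite-converted reads.

A read is tested exactly two ways against the forward reference (directional
protocol, methylated adapters): as-is under CT asymmetry (Watson-strand
origin) and reverse-complemented under GA asymmetry (Crick-strand origin).
Seeds from the conversion-tolerant k-mer index are clustered by diagonal;
clusters supported by at least ``min_seeds`` k-mers in close proximity become
candidate regions, which are scored with a banded Smith-Waterman local
alignment whose scoring function treats reference-C/read-T (or reference-G/
read-A) columns as full matches.  A read is mapped uniquely when a single
alignment attains the maximal score over all regions and both orientations;
unique hits below the bisulfite-excluded identity threshold are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

import numpy as np

from .kmer import (
    BASE_CODE,
    ConversionMode,
    GenomeIndex,
    encode_kmer,
    reverse_complement,
)

logger = logging.getLogger(__name__)

MIN_INT = -(2 ** 28)

# column codes in AlignmentResult.columns
MATCH = "="
BS_MATCH = "B"  # bisulfite-consistent: ref C / read T (CT) or ref G / read A (GA)
MISMATCH = "X"
INSERTION = "I"  # read base over a gap in the reference
DELETION = "D"  # reference base over a gap in the read


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores: bisulfite-consistent columns score as matches."""

    match: int = 4
    mismatch: int = -2
    gap: int = -10  # linear, per gap column

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch > self.gap):
            raise ValueError("require match > 0 > mismatch > gap")


class SeedHit(NamedTuple):
    """One k-mer shared (up to conversion) between read and genome."""

    read_offset: int
    genome_pos: int  # contig-local

    @property
    def diagonal(self) -> int:
        return self.genome_pos - self.read_offset


@dataclass(frozen=True)
class CandidateRegion:
    """A diagonal cluster of seed hits worth aligning against."""

    contig: str
    ref_start: int  # 0-based half-open, contig-local
    ref_end: int
    mode: ConversionMode
    n_seeds: int
    diagonal: int  # representative genome_pos - read_offset, contig-local


@dataclass
class AlignmentResult:
    """A scored local alignment with per-column classification.

    Coordinates are 0-based half-open; ``ref_start``/``ref_end`` are
    contig-local when ``contig`` is set, else relative to the window passed
    to :func:`sw_align`.  ``query`` is the sequence in aligned orientation
    (the reverse complement of the read for GA-mode hits).
    """

    score: int
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    columns: str
    mode: ConversionMode
    identity: float
    contig: Optional[str] = None
    query: str = ""

    def cigar(self) -> str:
        """CIGAR over the aligned region, with soft clips for the query ends."""
        ops = []
        if self.read_start:
            ops.append((self.read_start, "S"))
        for col in self.columns:
            op = "M" if col in "=BX" else col
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + 1, op)
            else:
                ops.append((1, op))
        tail = len(self.query) - self.read_end
        if tail:
            ops.append((tail, "S"))
        return "".join(f"{n}{op}" for n, op in ops)


@dataclass
class MappedRead:
    """Mapping outcome for one read."""

    read_id: str
    run_id: str
    status: str  # unique | ambiguous | unmapped | low_identity
    alignment: Optional[AlignmentResult] = None


@dataclass
class MappingStats:
    total: int = 0
    unique: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    low_identity: int = 0

    def add(self, status: str) -> None:
        self.total += 1
        setattr(self, status, getattr(self, status) + 1)


# ---------------------------------------------------------------------------
# banded Smith-Waterman kernel


def _encode_seq(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.uint8)  # 4 = N/other, matches nothing
    for i, b in enumerate(seq):
        out[i] = BASE_CODE.get(b, 4)
    return out


def _band_kernel_py(q, r, d0, w, match, mismatch, gap, ref_ok, read_ok):
    n = q.shape[0]
    m = r.shape[0]
    width = 2 * w + 1
    H = np.zeros((n + 1, width), dtype=np.int32)
    P = np.zeros((n + 1, width), dtype=np.int8)
    best = 0
    bi = 0
    bb = 0
    for i in range(1, n + 1):
        for b in range(width):
            j = i + d0 - w + b
            if j < 1 or j > m:
                H[i, b] = MIN_INT
                continue
            qb = q[i - 1]
            rb = r[j - 1]
            if qb == rb and qb < 4:
                s = match
            elif rb == ref_ok and qb == read_ok:
                s = match
            else:
                s = mismatch
            if i == 1 or j == 1:
                dv = 0
            else:
                dv = H[i - 1, b]
            if i == 1:
                uv = 0
            elif b + 1 < width:
                uv = H[i - 1, b + 1]
            else:
                uv = MIN_INT
            if j == 1:
                lv = 0
            elif b - 1 >= 0:
                lv = H[i, b - 1]
            else:
                lv = MIN_INT
            h = 0
            p = 0
            t = dv + s
            if t > h:
                h = t
                p = 1
            t = uv + gap
            if t > h:
                h = t
                p = 2
            t = lv + gap
            if t > h:
                h = t
                p = 3
            H[i, b] = h
            P[i, b] = p
            if h > best:
                best = h
                bi = i
                bb = b
    return best, bi, bb, H, P


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _band_kernel = njit(cache=True, nogil=True)(_band_kernel_py)
except Exception:  # pragma: no cover
    _band_kernel = _band_kernel_py
    logger.warning("numba unavailable; falling back to pure-Python alignment kernel")


def sw_align(
    query: str,
    ref_window: str,
    mode: ConversionMode,
    scoring: ScoringScheme = ScoringScheme(),
    band_halfwidth: int = 4,
    diagonal: int = 0,
) -> AlignmentResult:
    """Best local alignment of ``query`` to ``ref_window`` within a band.

    The band spans ``diagonal`` ± ``band_halfwidth`` (window-relative
    diagonals, diagonal = ref offset − query offset); passing
    ``band_halfwidth >= len(query) + len(ref_window)`` makes this a full
    Smith-Waterman.  Bisulfite-consistent columns (ref C/read T in CT mode,
    ref G/read A in GA mode) score as matches but are reported separately so
    identity can exclude them.  The empty alignment (score 0) is allowed.
    """
    if not query or not ref_window:
        raise ValueError("query and reference window must be non-empty")
    q = _encode_seq(query)
    r = _encode_seq(ref_window)
    ref_ok = BASE_CODE[mode.ref_base]
    read_ok = BASE_CODE[mode.read_base]
    best, bi, bb, H, P = _band_kernel(
        q,
        r,
        int(diagonal),
        int(band_halfwidth),
        scoring.match,
        scoring.mismatch,
        scoring.gap,
        ref_ok,
        read_ok,
    )
    if best <= 0:
        return AlignmentResult(
            0, 0, 0, 0, 0, "", mode, 0.0, query=query
        )
    # traceback
    w = int(band_halfwidth)
    i, b = bi, bb
    cols: List[str] = []
    while i > 0 and 0 <= b < 2 * w + 1 and H[i, b] > 0:
        p = P[i, b]
        j = i + diagonal - w + b
        if p == 1:
            qb, rb = q[i - 1], r[j - 1]
            if qb == rb and qb < 4:
                cols.append(MATCH)
            elif rb == ref_ok and qb == read_ok:
                cols.append(BS_MATCH)
            else:
                cols.append(MISMATCH)
            i -= 1
        elif p == 2:
            cols.append(INSERTION)
            i -= 1
            b += 1
        elif p == 3:
            cols.append(DELETION)
            b -= 1
        else:  # pragma: no cover - defensive
            break
    cols.reverse()
    columns = "".join(cols)
    read_start = i
    ref_start = i + diagonal - w + b
    ref_end = bi + diagonal - w + bb
    aln = AlignmentResult(
        score=int(best),
        ref_start=int(ref_start),
        ref_end=int(ref_end),
        read_start=int(read_start),
        read_end=int(bi),
        columns=columns,
        mode=mode,
        identity=0.0,
        query=query,
    )
    aln.identity = compute_identity(aln)
    return aln


def compute_identity(aln: AlignmentResult) -> float:
    """Fraction of aligned columns that match after excluding bisulfite
    mismatches (which count as matches); gap columns stay in the denominator.
    Empty alignments have identity 0."""
    total = len(aln.columns)
    if total == 0:
        return 0.0
    good = aln.columns.count(MATCH) + aln.columns.count(BS_MATCH)
    return good / total


# ---------------------------------------------------------------------------
# seeding


def find_candidate_regions(
    index: GenomeIndex,
    query: str,
    mode: ConversionMode,
    min_seeds: int = 2,
    offset_tol: int = 3,
) -> List[CandidateRegion]:
    """Diagonal-cluster seed hits of ``query`` into alignment candidates.

    Seeds are (read offset, genome position) pairs from the conversion-aware
    index; two seeds belong to the same cluster when their diagonals
    (genome position − read offset) differ by at most ``offset_tol`` — i.e.
    the k-mer spacing in read and genome may differ by that many bases.
    Clusters with fewer than ``min_seeds`` seeds are dropped.  Regions are
    padded by ``offset_tol + k`` and clipped to contig bounds.
    """
    k = index.k
    L = len(query)
    if L < k:
        return []
    blocked = mode.read_base
    seeds: List[Tuple[int, int]] = []  # (global diagonal, global genome pos)
    # rolling count of the converted base to apply t_exclusion cheaply
    for off in range(L - k + 1):
        kmer = query[off : off + k]
        if kmer.count(blocked) >= index.t_exclusion:
            continue
        try:
            value = encode_kmer(kmer).value
        except ValueError:
            continue
        for g in index._lookup_value(value, mode):
            seeds.append((g - off, g))
    if not seeds:
        return []
    seeds.sort()
    pad = offset_tol + k
    regions: List[CandidateRegion] = []

    def emit(cluster: List[Tuple[int, int]]) -> None:
        if len(cluster) < min_seeds:
            return
        gmin = min(g for _, g in cluster)
        gmax = max(g for _, g in cluster)
        ci = index.contig_of(gmin)
        if index.contig_of(gmax) != ci:  # spans contigs: not a real locus
            return
        name = index.contig_names[ci]
        offset = int(index.offsets[ci])
        clen = index.contig_lengths[name]
        start = max(0, gmin - offset - pad)
        end = min(clen, gmax - offset + L + pad)
        diags = sorted(d - offset for d, _ in cluster)
        regions.append(
            CandidateRegion(
                contig=name,
                ref_start=start,
                ref_end=end,
                mode=mode,
                n_seeds=len(cluster),
                diagonal=diags[len(diags) // 2],
            )
        )

    cluster = [seeds[0]]
    for s in seeds[1:]:
        if s[0] - cluster[-1][0] <= offset_tol and index.contig_of(
            s[1]
        ) == index.contig_of(cluster[0][1]):
            cluster.append(s)
        else:
            emit(cluster)
            cluster = [s]
    emit(cluster)
    return regions


# ---------------------------------------------------------------------------
# per-read driver


def map_read(
    read_id: str,
    seq: str,
    index: GenomeIndex,
    scoring: ScoringScheme = ScoringScheme(),
    min_identity: float = 0.85,
    min_seeds: int = 2,
    offset_tol: int = 3,
    band_halfwidth: int = 4,
    run_id: str = "run1",
) -> MappedRead:
    """Map one read; the status encodes every failure mode.

    The read is aligned as-is under CT and reverse-complemented under GA,
    always against the forward reference.  A strict-majority of one is
    required: any score tie across regions or orientations makes the read
    ambiguous.
    """
    seq = seq.upper()
    if len(seq) < index.k + 1:
        logger.warning("read %s shorter than k+1; reported unmapped", read_id)
        return MappedRead(read_id, run_id, "unmapped")
    queries = {
        ConversionMode.CT: seq,
        ConversionMode.GA: reverse_complement(seq),
    }
    alignments: Dict[Tuple, AlignmentResult] = {}
    for mode, query in queries.items():
        for region in find_candidate_regions(
            index, query, mode, min_seeds=min_seeds, offset_tol=offset_tol
        ):
            window = index.contig_seqs[region.contig][
                region.ref_start : region.ref_end
            ]
            aln = sw_align(
                query,
                window,
                mode,
                scoring,
                band_halfwidth=band_halfwidth,
                diagonal=region.diagonal - region.ref_start,
            )
            if aln.score <= 0:
                continue
            aln.contig = region.contig
            aln.ref_start += region.ref_start
            aln.ref_end += region.ref_start
            key = (mode, region.contig, aln.ref_start, aln.ref_end)
            prev = alignments.get(key)
            if prev is None or aln.score > prev.score:
                alignments[key] = aln
    if not alignments:
        return MappedRead(read_id, run_id, "unmapped")
    best = max(a.score for a in alignments.values())
    winners = [a for a in alignments.values() if a.score == best]
    if len(winners) > 1:
        return MappedRead(read_id, run_id, "ambiguous")
    aln = winners[0]
    if aln.identity < min_identity:
        return MappedRead(read_id, run_id, "low_identity", aln)
    return MappedRead(read_id, run_id, "unique", aln)


def map_library(
    reads: Iterable[Tuple[str, str]],
    index: GenomeIndex,
    scoring: ScoringScheme = ScoringScheme(),
    min_identity: float = 0.85,
    min_seeds: int = 2,
    offset_tol: int = 3,
    band_halfwidth: int = 4,
    run_id: str = "run1",
) -> Tuple[List[MappedRead], MappingStats]:
    """Map an iterable of (read_id, sequence) records; returns results + stats.

    Unreadable records are skipped with a warning; the stats counts always
    sum to the number of records attempted.
    """
    results: List[MappedRead] = []
    stats = MappingStats()
    for rec in reads:
        try:
            read_id, seq = rec[0], rec[1]
        except Exception:
            logger.warning("skipping unreadable read record %r", rec)
            continue
        mr = map_read(
            read_id,
            seq,
            index,
            scoring,
            min_identity=min_identity,
            min_seeds=min_seeds,
            offset_tol=offset_tol,
            band_halfwidth=band_halfwidth,
            run_id=run_id,
        )
        results.append(mr)
        stats.add(mr.status)
    return results, stats
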