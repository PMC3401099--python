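"""2-bit k-mer encoding and a bisulfite-conversion-tolerant genome seed index.

Bisulfite treatment deaminates unmethylated cytosine to uracil, so a read
derived from the converted Watson strand shows a T wherever the genome has an
unmethylated C, and a reverse-complemented read from the converted Crick
strand shows an A wherever the forward genome has a G.  Exact k-mer seeding
therefore breaks down.  Seeding is restored here with an *asymmetric*
look-up: for every genomic k-mer the index also stores the keys of all its
C->T substitution variants (and, for the opposite strand, all G->A variants),
so a fully or partially converted read k-mer still retrieves the genomic
positions it came from, while a read C never matches a genomic T — the
one-way nature of the chemistry is preserved.

k-mers are packed into integers two bits per base (A=00, C=01, G=10, T=11,
leftmost base most significant).  All coordinates are 0-based and intervals
half-open.
"""

from __future__ import annotations

import gzip
import json
import logging
from enum import Enum
from typing import Dict, Iterable, List, Mapping, NamedTuple, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: 2-bit code per nucleotide; leftmost base of a k-mer is most significant.
BASE_CODE: Dict[str, int] = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_BASE = "ACGT"

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_K = 12
DEFAULT_T_EXCLUSION = 8


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(COMPLEMENT)[::-1]


class ConversionMode(Enum):
    """Orientation of the bisulfite asymmetry.

    CT: the read comes from the converted Watson strand — a genomic C may be
    read as T.  GA: the read is the reverse complement of a converted Crick
    strand fragment, viewed in forward coordinates — a genomic G may be read
    as A.  The converse substitutions are never allowed.
    """

    CT = "CT"
    GA = "GA"

    @property
    def ref_base(self) -> str:
        """Reference base that may appear converted in the read."""
        return "C" if self is ConversionMode.CT else "G"

    @property
    def read_base(self) -> str:
        """Read base a converted reference base appears as."""
        return "T" if self is ConversionMode.CT else "A"


class KmerKey(NamedTuple):
    """Integer key of a k-mer under the 2-bit big-endian packing."""

    value: int
    k: int


def encode_kmer(kmer: str) -> KmerKey:
    """Pack a DNA string into its integer key.

    Raises ``ValueError`` on any character outside {A, C, G, T}; callers that
    slide a window over a sequence simply skip the offending k-mers.
    """
    value = 0
    for base in kmer:
        code = BASE_CODE.get(base)
        if code is None:
            raise ValueError(f"non-ACGT base {base!r} in k-mer {kmer!r}")
        value = (value << 2) | code
    return KmerKey(value, len(kmer))


def decode_key(key: KmerKey | int, k: int | None = None) -> str:
    """Inverse of :func:`encode_kmer`."""
    if isinstance(key, KmerKey):
        value, k = key.value, key.k
    else:
        if k is None:
            raise ValueError("k must be given when decoding a bare integer")
        value = key
    if not 0 <= value < 4 ** k:
        raise ValueError(f"key {value} out of range for k={k}")
    bases = []
    for shift in range(2 * (k - 1), -2, -2):
        bases.append(CODE_BASE[(value >> shift) & 0b11])
    return "".join(bases)


def _switchable_shifts(value: int, k: int, from_code: int) -> List[int]:
    """Bit shifts of the positions holding ``from_code`` in a packed k-mer."""
    shifts = []
    for i in range(k):
        shift = 2 * i
        if (value >> shift) & 0b11 == from_code:
            shifts.append(shift)
    return shifts


def _expand_values(value: int, k: int, from_code: int) -> List[int]:
    """All keys reachable by switching any subset of ``from_code`` positions.

    Both C(01)->T(11) and G(10)->A(00) flip exactly the high bit of the base
    pair, so every switch is an XOR with ``2 << shift``.  Includes the
    unswitched key itself; 2^(#switchable) values in total.
    """
    shifts = _switchable_shifts(value, k, from_code)
    out = [value]
    for shift in shifts:
        mask = 2 << shift
        out.extend([v ^ mask for v in out])
    return out


def expand_keys(kmer: str, mode: ConversionMode) -> set:
    """Keys of every conversion variant of ``kmer`` (including itself).

    Mode CT switches subsets of C positions to T; mode GA switches subsets of
    G positions to A.  The set has exactly 2^(#switchable bases) members.
    """
    key = encode_kmer(kmer)
    from_code = BASE_CODE[mode.ref_base]
    return {KmerKey(v, key.k) for v in _expand_values(key.value, key.k, from_code)}


def matches_under_conversion(ref_kmer: str, read_kmer: str, mode: ConversionMode) -> bool:
    """Position-wise compatibility of a read k-mer with a genomic k-mer.

    True iff at every position the bases are equal, or the reference has the
    convertible base and the read its converted form.  Asymmetric: a read C
    never matches a reference T (and a read G never a reference A).
    """
    if len(ref_kmer) != len(read_kmer):
        raise ValueError("k-mer lengths differ")
    rb, qb = mode.ref_base, mode.read_base
    return all(
        r == q or (r == rb and q == qb) for r, q in zip(ref_kmer, read_kmer)
    )


def _count_code(value: int, k: int, code: int) -> int:
    n = 0
    for i in range(k):
        if (value >> (2 * i)) & 0b11 == code:
            n += 1
    return n


class GenomeIndex:
    """Hash index of genomic k-mer positions with asymmetric bisulfite look-up.

    ``table`` maps each plain genomic k-mer key to the ascending list of its
    (global, 0-based) start positions on the forward strand.  Two derived
    tables key the same position lists by every C->T (respectively G->A)
    variant of the genomic k-mer, so that a converted read k-mer resolves its
    candidate loci with a single hash probe.  Variants containing
    ``t_exclusion`` or more of the converted base are not stored, and read
    k-mers that T-rich (A-rich in GA mode) are refused at query time — such
    seeds are too unspecific to be useful.
    """

    FORMAT = "biss-index"
    VERSION = 1

    def __init__(
        self,
        contigs: Mapping[str, str],
        k: int = DEFAULT_K,
        t_exclusion: int = DEFAULT_T_EXCLUSION,
        genome_id: str = "genome",
    ):
        if not contigs:
            raise ValueError("empty genome: nothing to index")
        if k < 4:
            raise ValueError("k must be at least 4")
        self.k = k
        self.t_exclusion = t_exclusion
        self.genome_id = genome_id
        self.contig_names: List[str] = list(contigs)
        self.contig_seqs: Dict[str, str] = {n: contigs[n].upper() for n in contigs}
        self.contig_lengths: Dict[str, int] = {
            n: len(s) for n, s in self.contig_seqs.items()
        }
        # offsets[i] = global coordinate of contig i's first base
        lengths = np.array([self.contig_lengths[n] for n in self.contig_names])
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.total_length = int(self.offsets[-1])
        self.table: Dict[int, List[int]] = {}
        self._variant_tables: Dict[ConversionMode, Dict[int, List[int]]] = {}
        self._build()

    # -- construction -----------------------------------------------------

    def _build(self) -> None:
        k = self.k
        mask = (1 << (2 * k)) - 1
        any_kmer = False
        for ci, name in enumerate(self.contig_names):
            seq = self.contig_seqs[name]
            if len(seq) < k:
                logger.warning(
                    "contig %s shorter than k=%d; no k-mers indexed", name, k
                )
                continue
            offset = int(self.offsets[ci])
            value = 0
            valid = 0  # number of consecutive valid bases ending here
            for pos, base in enumerate(seq):
                code = BASE_CODE.get(base)
                if code is None:
                    valid = 0
                    value = 0
                    continue
                value = ((value << 2) | code) & mask
                valid += 1
                if valid >= k:
                    start = pos - k + 1
                    self.table.setdefault(value, []).append(offset + start)
                    any_kmer = True
        if not any_kmer:
            logger.warning("genome shorter than k=%d everywhere; index is empty", k)
        for mode in ConversionMode:
            self._variant_tables[mode] = self._build_variants(mode)

    def _build_variants(self, mode: ConversionMode) -> Dict[int, List[int]]:
        from_code = BASE_CODE[mode.ref_base]
        to_code = BASE_CODE[mode.read_base]
        table: Dict[int, List[int]] = {}
        for value, positions in self.table.items():
            for variant in _expand_values(value, self.k, from_code):
                # a read k-mer equal to an excluded variant would itself be
                # refused at query time, so storing it is pointless
                if _count_code(variant, self.k, to_code) >= self.t_exclusion:
                    continue
                table.setdefault(variant, []).extend(positions)
        for positions in table.values():
            positions.sort()
        return table

    # -- coordinates ------------------------------------------------------

    def to_contig(self, gpos: int) -> Tuple[str, int]:
        """Split a global position into (contig name, contig-local position)."""
        ci = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.contig_names[ci], gpos - int(self.offsets[ci])

    def contig_of(self, gpos: int) -> int:
        """Index of the contig containing a global position."""
        return int(np.searchsorted(self.offsets, gpos, side="right")) - 1

    # -- queries ----------------------------------------------------------

    def _lookup_value(self, value: int, mode: ConversionMode) -> List[int]:
        """Global positions whose genomic k-mer has ``value`` as a variant."""
        return self._variant_tables[mode].get(value, [])

    def lookup(self, read_kmer: str, mode: ConversionMode) -> List[Tuple[str, int]]:
        """Candidate genomic loci of a (possibly converted) read k-mer.

        Returns (contig, 0-based position) pairs for every genomic k-mer that
        the read k-mer could have been derived from by conversion; empty when
        the k-mer carries ``t_exclusion`` or more of the converted base.
        """
        if len(read_kmer) != self.k:
            raise ValueError(
                f"query length {len(read_kmer)} != index k {self.k}"
            )
        key = encode_kmer(read_kmer)
        if read_kmer.count(mode.read_base) >= self.t_exclusion:
            return []
        return [self.to_contig(g) for g in self._lookup_value(key.value, mode)]

    # -- persistence ------------------------------------------------------

    def save(self, path: str) -> None:
        """Persist as gzipped JSON with a versioned header.

        The derived variant tables are rebuilt on load; only the plain
        genomic table and the sequences travel.
        """
        payload = {
            "format": self.FORMAT,
            "version": self.VERSION,
            "k": self.k,
            "t_exclusion": self.t_exclusion,
            "genome_id": self.genome_id,
            "contig_names": self.contig_names,
            "contig_seqs": self.contig_seqs,
        }
        with gzip.open(path, "wt") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "GenomeIndex":
        with gzip.open(path, "rt") as fh:
            payload = json.load(fh)
        if payload.get("format") != cls.FORMAT:
            raise ValueError(f"{path} is not a {cls.FORMAT} file")
        return cls(
            payload["contig_seqs"],
            k=payload["k"],
            t_exclusion=payload["t_exclusion"],
            genome_id=payload["genome_id"],
        )


def build_index(
    genome: Mapping[str, str] | Iterable[Tuple[str, str]],
    k: int = DEFAULT_K,
    t_exclusion: int = DEFAULT_T_EXCLUSION,
    genome_id: str = "genome",
) -> GenomeIndex:
    """Index every ACGT-only forward-strand k-mer of ``genome``.

    ``genome`` maps contig names to sequences (or is an iterable of
    (name, sequence) pairs).  Case-insensitive; k-mers overlapping any
    non-ACGT character are never indexed.
    """
    if not isinstance(genome, Mapping):
        genome = dict(genome)
    return GenomeIndex(genome, k=k, t_exclusion=t_exclusion, genome_id=genome_id)


def lookup_seed(
    index: GenomeIndex, read_kmer: str, mode: ConversionMode
) -> List[Tuple[str, int]]:
    """Functional wrapper around :meth:`GenomeIndex.lookup`."""
    return index.lookup(read_kmer, mode)
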