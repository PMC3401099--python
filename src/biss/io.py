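"""Standard-format readers and writers (FASTA, FASTQ, SAM, TSV, bedGraph).

All internal coordinates are 0-based half-open; SAM POS is converted to
1-based only at this boundary.  Every tabular output carries a commented
header block recording the tool version and the parameter snapshot, so any
file can be traced back to the settings that produced it.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO

from . import __version__
from .align import AlignmentResult, MappedRead
from .kmer import ConversionMode

logger = logging.getLogger(__name__)


def read_fasta(path: str) -> Dict[str, str]:
    """Contig name -> uppercased sequence (multi-line and softmasked OK)."""
    contigs: Dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str) -> List[Tuple[str, str]]:
    """(read_id, sequence) records from a 4-line FASTQ file."""
    reads: List[Tuple[str, str]] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(
                    f"{path}: truncated FASTQ record starting at line {lineno}"
                )
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(
                    f"{path}: malformed FASTQ record starting at line {lineno}"
                )
            seq = seq.strip().upper()
            if len(seq) != len(qual.strip()):
                raise ValueError(
                    f"{path}: sequence/quality length mismatch at line {lineno}"
                )
            reads.append((header[1:].split()[0], seq))
            lineno += 3
    return reads


def write_fastq(
    reads: Iterable[Tuple[str, str]], path: str, quality_char: str = "I"
) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def _parameter_header(params: Optional[Mapping[str, object]]) -> List[str]:
    lines = [f"biss_version={__version__}"]
    if params:
        lines.extend(f"{k}={v}" for k, v in sorted(params.items()))
    return lines


def sam_header(contigs: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in contigs.items()],
            "PG": [{"ID": "biss", "PN": "biss", "VN": __version__}],
        }
    )


def write_sam(
    mapped: Iterable[MappedRead],
    contigs: Mapping[str, str],
    path: str,
    run_id: str = "run1",
) -> int:
    """Write uniquely mapped reads as plain SAM; returns the records written.

    Flag 0 marks CT-mode (Watson-origin) hits, flag 16 GA-mode hits, whose
    stored sequence is the reverse complement of the raw read, as SAM
    requires.  Custom tags: AS alignment score, XI bisulfite-excluded
    identity, XB count of bisulfite-consistent columns, XR run identifier.
    """
    header = sam_header(contigs)
    names = list(contigs)
    n = 0
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for mr in mapped:
            if mr.status != "unique":
                continue
            aln = mr.alignment
            rec = pysam.AlignedSegment(header)
            rec.query_name = mr.read_id
            rec.query_sequence = aln.query
            rec.flag = 0 if aln.mode is ConversionMode.CT else 16
            rec.reference_id = names.index(aln.contig)
            rec.reference_start = aln.ref_start  # pysam is 0-based; SAM POS 1-based on disk
            rec.mapping_quality = 255
            rec.cigarstring = aln.cigar()
            rec.set_tags(
                [
                    ("AS", aln.score, "i"),
                    ("XI", float(aln.identity), "f"),
                    ("XB", aln.columns.count("B"), "i"),
                    ("XR", mr.run_id or run_id, "Z"),
                ]
            )
            out.write(rec)
            n += 1
    return n


def read_sam(path: str, default_run_id: Optional[str] = None) -> Dict[str, List[MappedRead]]:
    """Reconstruct unique alignments from a SAM file, grouped by run.

    The conversion mode is recovered from the strand flag and the per-column
    classification from the CIGAR plus the stored sequence; this is enough
    for pileup building (which re-reads the reference itself).
    """
    by_run: Dict[str, List[MappedRead]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            mode = ConversionMode.GA if rec.is_reverse else ConversionMode.CT
            columns = []
            read_start = None
            for op, length in rec.cigartuples:
                if op == 4:  # soft clip
                    if read_start is None:
                        read_start = length
                    continue
                if read_start is None:
                    read_start = 0
                if op == 0:
                    columns.append("M" * length)
                elif op == 1:
                    columns.append("I" * length)
                elif op == 2:
                    columns.append("D" * length)
                else:
                    raise ValueError(f"unsupported CIGAR op {op} in {path}")
            cols = "".join(columns)
            # "M" placeholder columns suffice for pileup; re-classification
            # against the reference happens there anyway.
            cols = cols.replace("M", "=")
            n_read = cols.count("=") + cols.count("I")
            aln = AlignmentResult(
                score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                read_start=read_start or 0,
                read_end=(read_start or 0) + n_read,
                columns=cols,
                mode=mode,
                identity=float(rec.get_tag("XI")) if rec.has_tag("XI") else 1.0,
                contig=rec.reference_name,
                query=rec.query_sequence,
            )
            run_id = (
                rec.get_tag("XR")
                if rec.has_tag("XR")
                else (default_run_id or "run1")
            )
            by_run.setdefault(run_id, []).append(
                MappedRead(rec.query_name, run_id, "unique", aln)
            )
    return by_run


def write_tsv(
    df: pd.DataFrame, path: str, params: Optional[Mapping[str, object]] = None
) -> None:
    """TSV with a commented provenance header block."""
    with open(path, "w") as fh:
        for line in _parameter_header(params):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_bedgraph(
    calls: pd.DataFrame, path: str, params: Optional[Mapping[str, object]] = None
) -> None:
    """Methylation levels as single-base bedGraph intervals (0-based, half-open)."""
    defined = calls[calls["level"].notna()]
    with open(path, "w") as fh:
        for line in _parameter_header(params):
            fh.write(f"# {line}\n")
        fh.write('track type=bedGraph name="methylation_level"\n')
        for row in defined.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.pos}\t{row.pos + 1}\t{row.level:.4f}\n")
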