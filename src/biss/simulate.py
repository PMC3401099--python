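"""Synthetic bisulfite-sequencing data with known ground truth.

Generates a random genome, assigns each cytosine (both strands) a
methylation state by sequence context, and emits single-end reads through a
simple model of the bisulfite chemistry: per covered cytosine on the
originating strand, the read shows a C when the individual molecule was
methylated (a Bernoulli draw from the site's methylation degree theta),
otherwise a T with the run's conversion rate (failed conversions leave a C);
uniform substitution sequencing errors are applied afterwards.  Reads drawn
from the Crick strand are emitted as the converted Crick sequence, so a
mapper must reverse-complement them to place them on the forward reference.

The default configuration mirrors a plant-like study design: an AT-rich
genome (GC 0.36), CG-dominated methylation propensities, partial methylation
degrees drawn from a right-skewed Beta, 56-bp reads in several runs whose
bisulfite conversion rates differ — the run-to-run variability that makes
per-run majority voting worthwhile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import MappedRead
from .caller import classify_context
from .kmer import reverse_complement

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    ``reads_per_run`` defaults to the count giving ``mean_coverage`` total
    sequencing depth across all runs.  ``conversion_rates`` is the per-run
    probability that an *unmethylated* C is actually converted; values below
    1 model incomplete bisulfite treatment.  ``strand_prob`` is the chance a
    read originates from the Watson strand.
    """

    genome_length: int = 100_000
    gc_fraction: float = 0.36
    propensities: Dict[str, float] = field(
        default_factory=lambda: {"CG": 0.24, "CHG": 0.07, "CHH": 0.02}
    )
    beta_shape: Tuple[float, float] = (5.0, 1.0)
    n_runs: int = 3
    read_length: int = 56
    mean_coverage: float = 20.0
    reads_per_run: Optional[int] = None
    conversion_rates: Tuple[float, ...] = (0.995, 0.99, 0.90)
    sequencing_error_rate: float = 0.005
    strand_prob: float = 0.5
    contig_name: str = "chr1"

    def __post_init__(self):
        probs = [
            self.gc_fraction,
            self.sequencing_error_rate,
            self.strand_prob,
            *self.propensities.values(),
            *self.conversion_rates,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if len(self.conversion_rates) != self.n_runs:
            raise ValueError("need one conversion rate per run")

    @property
    def run_ids(self) -> List[str]:
        return [f"run{i + 1}" for i in range(self.n_runs)]

    def effective_reads_per_run(self) -> int:
        if self.reads_per_run is not None:
            return self.reads_per_run
        total_bases = self.mean_coverage * self.genome_length
        return int(np.ceil(total_bases / (self.read_length * self.n_runs)))


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> Dict[str, str]:
    """I.i.d. random genome at the configured GC fraction."""
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(list(_BASES), size=config.genome_length, p=p)
    return {config.contig_name: "".join(bases)}


def assign_methylome(
    genome: Mapping[str, str], config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Ground-truth methylome: one row per cytosine site on either strand.

    A site is methylated with its context's propensity (NA contexts never
    are); methylated sites draw a degree theta from the configured Beta,
    unmethylated sites have theta 0.
    """
    a, b = config.beta_shape
    rows = []
    for contig in sorted(genome):
        seq = genome[contig]
        for pos, base in enumerate(seq):
            if base == "C":
                strand = "+"
            elif base == "G":
                strand = "-"
            else:
                continue
            context = classify_context(genome, contig, pos, strand)
            prop = config.propensities.get(context, 0.0)
            methylated = bool(rng.random() < prop)
            theta = float(rng.beta(a, b)) if methylated else 0.0
            rows.append(
                {
                    "contig": contig,
                    "pos": pos,
                    "strand": strand,
                    "context": context,
                    "methylated": methylated,
                    "theta": theta,
                }
            )
    return pd.DataFrame(rows)


def _theta_arrays(
    genome: Mapping[str, str], truth: pd.DataFrame
) -> Dict[str, Dict[str, np.ndarray]]:
    """theta indexed by contig, strand and position for O(1) lookup."""
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for contig in genome:
        L = len(genome[contig])
        out[contig] = {"+": np.zeros(L), "-": np.zeros(L)}
    for row in truth.itertuples(index=False):
        out[row.contig][row.strand][row.pos] = row.theta
    return out


def simulate_reads(
    genome: Mapping[str, str],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[Dict[str, List[Tuple[str, str]]], pd.DataFrame]:
    """Per-run read lists plus a truth table of read origins.

    Returns ``(reads_by_run, origins)`` where reads are (read_id, sequence)
    pairs and origins records contig, 0-based fragment start on the forward
    strand, and originating strand for every read.
    """
    theta = _theta_arrays(genome, truth)
    contigs = sorted(genome)
    lengths = np.array([len(genome[c]) for c in contigs], dtype=float)
    contig_p = lengths / lengths.sum()
    L = config.read_length
    reads_by_run: Dict[str, List[Tuple[str, str]]] = {}
    origin_rows = []
    for run_idx, run_id in enumerate(config.run_ids):
        conv = config.conversion_rates[run_idx]
        err = config.sequencing_error_rate
        reads: List[Tuple[str, str]] = []
        n_reads = config.effective_reads_per_run()
        for i in range(n_reads):
            ci = rng.choice(len(contigs), p=contig_p) if len(contigs) > 1 else 0
            contig = contigs[ci]
            seq = genome[contig]
            start = int(rng.integers(0, len(seq) - L + 1))
            watson = bool(rng.random() < config.strand_prob)
            bases = []
            if watson:
                for j in range(start, start + L):
                    base = seq[j]
                    if base == "C":
                        bases.append(
                            _converted_base(theta[contig]["+"][j], conv, rng)
                        )
                    else:
                        bases.append(base)
            else:
                # read 5'->3' along the Crick strand: forward end to start
                for j in range(start + L - 1, start - 1, -1):
                    base = _COMP.get(seq[j], "N")
                    if base == "C":  # forward G, Crick cytosine
                        bases.append(
                            _converted_base(theta[contig]["-"][j], conv, rng)
                        )
                    else:
                        bases.append(base)
            if err > 0:
                for j in range(L):
                    if rng.random() < err:
                        alternatives = [b for b in _BASES if b != bases[j]]
                        bases[j] = alternatives[int(rng.integers(0, 3))]
            read_id = f"{run_id}_{i}"
            reads.append((read_id, "".join(bases)))
            origin_rows.append(
                {
                    "read_id": read_id,
                    "run_id": run_id,
                    "contig": contig,
                    "start": start,
                    "strand": "+" if watson else "-",
                }
            )
        reads_by_run[run_id] = reads
    return reads_by_run, pd.DataFrame(origin_rows)


def _converted_base(theta: float, conversion_rate: float, rng) -> str:
    """Read base emitted for one cytosine on the originating strand."""
    if theta > 0 and rng.random() < theta:
        return "C"  # this molecule was methylated: protected from conversion
    return "T" if rng.random() < conversion_rate else "C"


def simulate_experiment(
    config: SimulationConfig, seed: int
) -> Tuple[Dict[str, str], pd.DataFrame, Dict[str, List[Tuple[str, str]]], pd.DataFrame]:
    """Genome, truth methylome, reads and origins from one seed."""
    rng = np.random.default_rng(seed)
    genome = simulate_genome(config, rng)
    truth = assign_methylome(genome, config, rng)
    reads, origins = simulate_reads(genome, truth, config, rng)
    return genome, truth, reads, origins


# ---------------------------------------------------------------------------
# ground-truth scoring


def evaluate_mapping(
    mapped_by_run: Mapping[str, Sequence[MappedRead]],
    origins: pd.DataFrame,
    offset_tol: int = 0,
) -> Dict[str, float]:
    """Fraction of reads mapped uniquely, and placed at their true origin.

    A unique hit is position-correct when the inferred fragment start
    (``ref_start - read_start`` in aligned orientation) is within
    ``offset_tol`` of the simulated start, on the right contig and strand.
    """
    truth = {
        row.read_id: (row.contig, row.start, row.strand)
        for row in origins.itertuples(index=False)
    }
    total = unique = correct = 0
    for reads in mapped_by_run.values():
        for mr in reads:
            total += 1
            if mr.status != "unique":
                continue
            unique += 1
            aln = mr.alignment
            contig, start, strand = truth[mr.read_id]
            inferred = aln.ref_start - aln.read_start
            mode_strand = "+" if aln.mode.value == "CT" else "-"
            if (
                aln.contig == contig
                and mode_strand == strand
                and abs(inferred - start) <= offset_tol
            ):
                correct += 1
    return {
        "total": total,
        "unique": unique,
        "frac_unique": unique / total if total else 0.0,
        "frac_correct_of_unique": correct / unique if unique else 0.0,
    }


def evaluate_calls(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    min_coverage_rmse: int = 10,
) -> Dict[str, float]:
    """Precision/recall of M calls, status accuracy and level RMSE vs truth.

    Precision and recall treat truth-methylated as theta > 0 and are
    computed over sites with a determinate status (M or U); status accuracy
    is the fraction of those sites where (status == M) coincides with the
    truth flag.  RMSE compares the C/(C+T) level with theta on M sites with
    pooled coverage at least ``min_coverage_rmse``.
    """
    merged = calls.merge(
        truth[["contig", "pos", "strand", "theta"]],
        on=["contig", "pos", "strand"],
        how="inner",
        validate="one_to_one",
    )
    det = merged[merged["status"] != "X"]
    pred_m = det["status"] == "M"
    true_m = det["theta"] > 0
    tp = int((pred_m & true_m).sum())
    fp = int((pred_m & ~true_m).sum())
    fn = int((~pred_m & true_m).sum())
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    accuracy = float((pred_m == true_m).mean()) if len(det) else np.nan
    m_deep = det[pred_m & (det["n"] >= min_coverage_rmse)]
    rmse = (
        float(np.sqrt(np.mean((m_deep["level"] - m_deep["theta"]) ** 2)))
        if len(m_deep)
        else np.nan
    )
    return {
        "n_sites": len(merged),
        "n_determined": len(det),
        "precision_M": precision,
        "recall_M": recall,
        "status_accuracy": accuracy,
        "rmse_level": rmse,
    }


def evaluate(result, truth: pd.DataFrame, **kwargs) -> Dict[str, float]:
    """Dispatch to mapping or calling evaluation by result type."""
    if isinstance(result, pd.DataFrame):
        return evaluate_calls(result, truth, **kwargs)
    return evaluate_mapping(result, truth, **kwargs)
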