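"""Per-cytosine pileups and statistical methylcytosine calling.

Every genomic cytosine — a forward-strand C (Watson, strand ``+``) or a
forward-strand G, i.e. a Crick-strand C (strand ``-``) — is an independent
site.  Evidence is strictly directional: Watson sites accumulate bases only
from CT-mode alignments (read C = retained methylcytosine, read T =
converted unmethylated C), Crick sites only from GA-mode alignments (read G
methylated, read A converted, in forward projection).  Bases that are
neither signal the read may be misaligned and feed the *adaptive error*:
the binomial error rate at a site is the larger of the baseline
sequencing/conversion error (0.04) and the local non-C/T base frequency.

Calling proceeds in two stages.  First the runs are pooled: sites with
pooled C+T coverage below ``min_coverage`` are undetermined (X); the rest
get a one-sided binomial test of the methylated-read count against the
site's error rate, Benjamini–Hochberg corrected across the tested set, with
adjusted p < alpha marking a preliminary methylated (M) call.  Second,
preliminary M sites are re-tested run by run (again requiring the coverage
floor within the run): a strict majority of testable runs must confirm
methylation, otherwise the site is demoted to unmethylated (U); when no
single run has sufficient coverage, the pooled decision stands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .align import MappedRead
from .kmer import ConversionMode

logger = logging.getLogger(__name__)

DEFAULT_P0 = 0.04
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COVERAGE = 2

SiteKey = Tuple[str, int, str]  # (contig, 0-based forward position, strand)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SitePileup:
    """Per-run base counts at one genomic cytosine."""

    contig: str
    pos: int
    strand: str  # '+' Watson C, '-' Crick C (forward-strand G)
    context: str = "NA"
    runs: Dict[str, List[int]] = field(default_factory=dict)  # run -> [C, T, other]

    def counts(self, run_id: Optional[str] = None) -> Tuple[int, int, int]:
        """(n_C, n_T, n_other), pooled over runs unless one is named."""
        if run_id is not None:
            c, t, o = self.runs.get(run_id, (0, 0, 0))
            return c, t, o
        c = t = o = 0
        for cc, tt, oo in self.runs.values():
            c += cc
            t += tt
            o += oo
        return c, t, o


@dataclass(frozen=True)
class ErrorModel:
    """Baseline and per-site binomial error rate."""

    p0: float
    p_site: float


def classify_context(genome: Mapping[str, str], contig: str, pos: int, strand: str) -> str:
    """Sequence context (CG / CHG / CHH, H = A, C or T) of a cytosine.

    The two bases 3' of the cytosine on its own strand are read; for Crick
    sites that means positions ``pos-1`` and ``pos-2`` complemented.  Sites
    whose context runs off the contig or through a non-ACGT base are NA.
    """
    seq = genome[contig]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{contig}:{pos}+ is not a C")
        b1 = seq[pos + 1] if pos + 1 < len(seq) else None
        b2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{contig}:{pos}- is not a Crick C")
        b1 = _COMP.get(seq[pos - 1]) if pos - 1 >= 0 else None
        b2 = _COMP.get(seq[pos - 2]) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"bad strand {strand!r}")
    if b1 is None or b1 not in "ACGT":
        return "NA"
    if b1 == "G":
        return "CG"
    if b2 is None or b2 not in "ACGT":
        return "NA"
    if b2 == "G":
        return "CHG"
    return "CHH"


def pileup(
    alignments_by_run: Mapping[str, Iterable[MappedRead]],
    genome: Mapping[str, str],
) -> Dict[SiteKey, SitePileup]:
    """Accumulate per-run base counts over genomic cytosines.

    Only uniquely mapped reads may be passed.  CT-mode alignments contribute
    at Watson C sites, GA-mode alignments at Crick C sites (forward-strand
    Gs); gap columns contribute nothing.  Contexts are classified lazily for
    covered sites only.
    """
    sites: Dict[SiteKey, SitePileup] = {}
    for run_id, reads in alignments_by_run.items():
        for mr in reads:
            if mr.status != "unique":
                raise ValueError(
                    f"read {mr.read_id}: pileup accepts unique alignments only"
                )
            aln = mr.alignment
            if aln.contig not in genome:
                raise KeyError(f"alignment references unknown contig {aln.contig}")
            seq = genome[aln.contig]
            is_ct = aln.mode is ConversionMode.CT
            ref_base = "C" if is_ct else "G"
            strand = "+" if is_ct else "-"
            meth_base = "C" if is_ct else "G"
            conv_base = "T" if is_ct else "A"
            qi = aln.read_start
            rj = aln.ref_start
            for col in aln.columns:
                if col == "I":
                    qi += 1
                    continue
                if col == "D":
                    rj += 1
                    continue
                if seq[rj] == ref_base:
                    key = (aln.contig, rj, strand)
                    site = sites.get(key)
                    if site is None:
                        site = SitePileup(aln.contig, rj, strand)
                        sites[key] = site
                    counts = site.runs.setdefault(run_id, [0, 0, 0])
                    qb = aln.query[qi]
                    if qb == meth_base:
                        counts[0] += 1
                    elif qb == conv_base:
                        counts[1] += 1
                    else:
                        counts[2] += 1
                qi += 1
                rj += 1
    for key, site in sites.items():
        site.context = classify_context(genome, *key)
    return sites


def adaptive_error(site: SitePileup, p0: float = DEFAULT_P0, run_id: Optional[str] = None) -> ErrorModel:
    """Per-site error: the larger of the baseline and the non-C/T fraction."""
    n_c, n_t, n_o = site.counts(run_id)
    depth = n_c + n_t + n_o
    if depth == 0:
        raise ValueError("adaptive_error on a site with zero depth")
    f = n_o / depth
    return ErrorModel(p0=p0, p_site=min(max(p0, f), 1 - 1e-9))


def binom_pvalue(m: int, n: int, p: float) -> float:
    """Exact one-sided upper-tail P(X >= m) for X ~ Binomial(n, p)."""
    if not 0 <= m <= n:
        raise ValueError(f"need 0 <= m <= n, got m={m}, n={n}")
    if not 0 < p < 1:
        raise ValueError(f"need 0 < p < 1, got p={p}")
    return float(binom.sf(m - 1, n, p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def _test_sites(
    sites: List[SitePileup],
    p0: float,
    run_id: Optional[str] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized binomial test over a tested set: (p_raw, p_adj, p_site)."""
    m = np.empty(len(sites), dtype=np.int64)
    n = np.empty(len(sites), dtype=np.int64)
    ps = np.empty(len(sites), dtype=float)
    for i, site in enumerate(sites):
        n_c, n_t, _ = site.counts(run_id)
        m[i] = n_c
        n[i] = n_c + n_t
        ps[i] = adaptive_error(site, p0, run_id).p_site
    p_raw = binom.sf(m - 1, n, ps)
    return p_raw, bh_adjust(p_raw), ps


def call_pooled(
    pileups: Mapping[SiteKey, SitePileup],
    p0: float = DEFAULT_P0,
    alpha: float = DEFAULT_ALPHA,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Preliminary pooled-run calls, one row per covered site.

    Coverage ``n`` counts only C/T-evidence bases; other bases raise the
    adaptive error instead.  BH correction runs over exactly the tested set
    (pooled n >= min_coverage).
    """
    keys = sorted(pileups)
    rows = []
    tested_idx = []
    tested_sites = []
    for i, key in enumerate(keys):
        site = pileups[key]
        n_c, n_t, n_o = site.counts()
        n = n_c + n_t
        level = n_c / n if n > 0 else np.nan
        rows.append(
            {
                "contig": key[0],
                "pos": key[1],
                "strand": key[2],
                "context": site.context,
                "n_C": n_c,
                "n_T": n_t,
                "n_other": n_o,
                "n": n,
                "level": level,
                "p_raw": np.nan,
                "p_adj": np.nan,
                "p_site": np.nan,
                "status": "X",
            }
        )
        if n >= min_coverage:
            tested_idx.append(i)
            tested_sites.append(site)
    columns = [
        "contig", "pos", "strand", "context", "n_C", "n_T", "n_other",
        "n", "level", "p_raw", "p_adj", "p_site", "status",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if tested_sites:
        p_raw, p_adj, p_site = _test_sites(tested_sites, p0)
        idx = np.array(tested_idx)
        df.loc[idx, "p_raw"] = p_raw
        df.loc[idx, "p_adj"] = p_adj
        df.loc[idx, "p_site"] = p_site
        df.loc[idx, "status"] = np.where(p_adj < alpha, "M", "U")
    return df


def refine_by_runs(
    preliminary: pd.DataFrame,
    pileups: Mapping[SiteKey, SitePileup],
    p0: float = DEFAULT_P0,
    alpha: float = DEFAULT_ALPHA,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Demote pooled M calls that a majority of individual runs do not back.

    Only the preliminary methylated list is re-examined: within each run,
    every preliminary-M site whose run coverage reaches the floor is
    re-tested (binomial with the run's own adaptive error, BH-corrected
    across that run's re-tested set) and votes M when its adjusted p falls
    below alpha.  A site stays M only under a strict majority of its
    testable runs; with zero testable runs the pooled decision stands.
    U and X sites pass through unchanged.
    """
    calls = preliminary.copy()
    calls["runs_testable"] = 0
    calls["runs_voting_M"] = 0
    run_ids = sorted({r for site in pileups.values() for r in site.runs})
    keys = [
        (row.contig, row.pos, row.strand) for row in calls.itertuples(index=False)
    ]
    key_to_row = {key: i for i, key in enumerate(keys)}
    prelim_m = sorted(
        key for key, status in zip(keys, calls["status"]) if status == "M"
    )
    votes: Dict[SiteKey, List[bool]] = {}
    for run_id in run_ids:
        tested_keys = []
        tested_sites = []
        for key in prelim_m:
            site = pileups.get(key)
            if site is None:
                continue
            n_c, n_t, _ = site.counts(run_id)
            if n_c + n_t >= min_coverage:
                tested_keys.append(key)
                tested_sites.append(site)
        if not tested_sites:
            continue
        _, p_adj, _ = _test_sites(tested_sites, p0, run_id)
        for key, padj in zip(tested_keys, p_adj):
            votes.setdefault(key, []).append(bool(padj < alpha))
    testable = np.zeros(len(calls), dtype=int)
    voting = np.zeros(len(calls), dtype=int)
    for key, vote_list in votes.items():
        i = key_to_row.get(key)
        if i is not None:
            testable[i] = len(vote_list)
            voting[i] = sum(vote_list)
    calls["runs_testable"] = testable
    calls["runs_voting_M"] = voting
    is_m = calls["status"] == "M"
    demote = is_m & (testable > 0) & ~(voting * 2 > testable)
    calls.loc[demote, "status"] = "U"
    return calls


def all_cytosine_sites(genome: Mapping[str, str]) -> List[SiteKey]:
    """Every genomic cytosine on both strands, sorted."""
    sites: List[SiteKey] = []
    for contig in sorted(genome):
        seq = genome[contig]
        for pos, base in enumerate(seq):
            if base == "C":
                sites.append((contig, pos, "+"))
            elif base == "G":
                sites.append((contig, pos, "-"))
    return sites


def call_methylome(
    alignments_by_run: Mapping[str, Iterable[MappedRead]],
    genome: Mapping[str, str],
    p0: float = DEFAULT_P0,
    alpha: float = DEFAULT_ALPHA,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Full pipeline: pileup, pooled test, per-run refinement.

    Returns one row per genomic cytosine (both strands, including uncovered
    ones, which are X), sorted by (contig, pos, strand).
    """
    piles = pileup(alignments_by_run, genome)
    prelim = call_pooled(piles, p0=p0, alpha=alpha, min_coverage=min_coverage)
    refined = refine_by_runs(
        prelim, piles, p0=p0, alpha=alpha, min_coverage=min_coverage
    )
    covered = {
        (row.contig, row.pos, row.strand) for row in refined.itertuples(index=False)
    }
    missing_rows = []
    for key in all_cytosine_sites(genome):
        if key in covered:
            continue
        missing_rows.append(
            {
                "contig": key[0],
                "pos": key[1],
                "strand": key[2],
                "context": classify_context(genome, *key),
                "n_C": 0,
                "n_T": 0,
                "n_other": 0,
                "n": 0,
                "level": np.nan,
                "p_raw": np.nan,
                "p_adj": np.nan,
                "p_site": np.nan,
                "status": "X",
                "runs_testable": 0,
                "runs_voting_M": 0,
            }
        )
    if missing_rows:
        refined = pd.concat([refined, pd.DataFrame(missing_rows)], ignore_index=True)
    refined = refined.sort_values(["contig", "pos", "strand"]).reset_index(drop=True)
    return refined
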