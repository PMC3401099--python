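"""Downstream methylome analytics.

Operates on call tables (one row per genomic cytosine with status M/U/X,
context and C/(C+T) level) as produced by :mod:`biss.caller`: global
methylation rates, context distributions, congruency between two call sets,
level histograms, validation correlations, raw-read C fractions and a
window scan for validation candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .caller import all_cytosine_sites, classify_context

STATUSES = ("M", "U", "X")
CONTEXTS = ("CG", "CHG", "CHH")

SITE_COLS = ["contig", "pos", "strand"]


@dataclass
class CongruencyMatrix:
    """Joint status counts of two call sets over the same site universe."""

    counts: pd.DataFrame  # 3x3, rows = set A status, cols = set B status
    total: int

    @property
    def percent(self) -> pd.DataFrame:
        """Cells as percentages of all cytosines."""
        return 100.0 * self.counts / self.total

    def marginal_a(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def marginal_b(self) -> pd.Series:
        return self.counts.sum(axis=0)


def global_rate(calls: pd.DataFrame) -> Dict[str, float]:
    """Global methylation rate, by both denominators.

    ``of_all``: M / (M+U+X), the fraction of all genomic cytosines;
    ``of_classified``: M / (M+U), the fraction of cytosines whose status
    could be determined.
    """
    if len(calls) == 0:
        raise ValueError("empty call set")
    n = len(calls)
    n_m = int((calls["status"] == "M").sum())
    n_x = int((calls["status"] == "X").sum())
    classified = n - n_x
    return {
        "of_all": n_m / n,
        "of_classified": n_m / classified if classified else np.nan,
    }


def context_distribution(
    source, subset: str = "all", genome: Optional[Mapping[str, str]] = None
) -> pd.Series:
    """Fractions of CG / CHG / CHH, NA excluded.

    ``source`` is either a call table (``subset`` may be "all" or
    "methylated") or a genome mapping, in which case contexts of every
    cytosine are computed from the sequence alone.
    """
    if isinstance(source, pd.DataFrame):
        df = source
        if subset == "methylated":
            df = df[df["status"] == "M"]
        elif subset != "all":
            raise ValueError(f"unknown subset {subset!r}")
        contexts = df["context"]
    else:
        contexts = pd.Series(
            [classify_context(source, *site) for site in all_cytosine_sites(source)]
        )
    counts = contexts.value_counts().reindex(CONTEXTS, fill_value=0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no classifiable cytosine contexts")
    return counts / total


def congruency(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> CongruencyMatrix:
    """3x3 M/U/X cross-tabulation of two call sets on shared coordinates."""
    merged = calls_a[SITE_COLS + ["status"]].merge(
        calls_b[SITE_COLS + ["status"]],
        on=SITE_COLS,
        how="inner",
        suffixes=("_a", "_b"),
        validate="one_to_one",
    )
    if len(merged) != len(calls_a) or len(merged) != len(calls_b):
        raise ValueError("call sets cover different site universes")
    table = pd.crosstab(merged["status_a"], merged["status_b"])
    table = table.reindex(index=STATUSES, columns=STATUSES, fill_value=0)
    table.index.name = "A"
    table.columns.name = "B"
    return CongruencyMatrix(counts=table, total=len(merged))


def level_histogram(
    calls: pd.DataFrame,
    n_bins: int = 20,
    what_if_threshold: float = 0.4,
) -> Dict[str, object]:
    """Histogram of C/(C+T) levels, split by M versus not-M status.

    Bins are half-open on [0, 1] with the last bin closed.  Also reports the
    fraction of M sites whose level is below one half — evidence of partial
    methylation the conservative test still accepted — and the what-if
    methylation rate (of classified sites) obtained when every site with a
    level above ``what_if_threshold`` is additionally counted as methylated.
    """
    defined = calls[calls["level"].notna()]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    is_m = defined["status"] == "M"
    counts_m, _ = np.histogram(defined.loc[is_m, "level"], bins=edges)
    counts_u, _ = np.histogram(defined.loc[~is_m, "level"], bins=edges)
    m_levels = defined.loc[is_m, "level"]
    frac_m_below_half = float((m_levels < 0.5).mean()) if len(m_levels) else np.nan
    classified = calls[calls["status"] != "X"]
    if len(classified):
        as_m = (classified["status"] == "M") | (
            classified["level"] > what_if_threshold
        )
        what_if = float(as_m.mean())
    else:
        what_if = np.nan
    return {
        "bin_edges": edges,
        "counts_M": counts_m,
        "counts_not_M": counts_u,
        "frac_M_below_half": frac_m_below_half,
        "what_if_rate_of_classified": what_if,
    }


def level_correlation(calls: pd.DataFrame, reference_levels: pd.DataFrame) -> float:
    """Pearson correlation of called levels with an independent level set.

    ``reference_levels`` needs the site columns plus a ``level`` column.
    Sites with an undefined level on either side are excluded; at least two
    shared sites are required.
    """
    merged = calls[SITE_COLS + ["level"]].merge(
        reference_levels[SITE_COLS + ["level"]],
        on=SITE_COLS,
        how="inner",
        suffixes=("_call", "_ref"),
    )
    merged = merged.dropna(subset=["level_call", "level_ref"])
    if len(merged) < 2:
        raise ValueError("need at least two shared sites with defined levels")
    r, _ = pearsonr(merged["level_call"], merged["level_ref"])
    return float(r)


def raw_read_c_fraction(
    reads_by_run: Mapping[str, Iterable[Tuple[str, str]]]
) -> Dict[str, float]:
    """Fraction of C among called (ACGT) bases, per run and pooled.

    With methylated adapters, every raw-read C should stem from a methylated
    genomic cytosine (or a conversion/sequencing error), so this fraction is
    a quick, mapping-free check on run quality and conversion efficiency.
    """
    out: Dict[str, float] = {}
    pooled_c = pooled_n = 0
    for run_id, reads in reads_by_run.items():
        c = n = 0
        for _, seq in reads:
            for base in seq:
                if base in "ACGT":
                    n += 1
                    if base == "C":
                        c += 1
        if n == 0:
            raise ValueError(f"run {run_id} contains no called bases")
        out[run_id] = c / n
        pooled_c += c
        pooled_n += n
    out["pooled"] = pooled_c / pooled_n
    return out


def scan_validation_windows(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    genome: Mapping[str, str],
    win_min: int = 250,
    win_max: int = 500,
    min_c_content: float = 0.30,
    size_step: int = 50,
    stride: Optional[int] = None,
) -> pd.DataFrame:
    """Candidate validation regions ranked by congruency-category purity.

    Windows of ``win_min``..``win_max`` bp (stepping sizes by ``size_step``,
    starts by ``stride``, default half the window) are kept when their
    C-content — cytosines on both strands, i.e. C+G of the forward sequence,
    over the window length — reaches ``min_c_content``.  Each window is
    labeled with its dominant joint category (M/M, U/U, M/U, ...) among the
    determinate sites it covers and its purity, the dominant category's
    fraction.
    """
    merged = calls_a[SITE_COLS + ["status"]].merge(
        calls_b[SITE_COLS + ["status"]],
        on=SITE_COLS,
        how="inner",
        suffixes=("_a", "_b"),
    )
    merged["category"] = (
        merged["status_a"].astype(str) + "/" + merged["status_b"].astype(str)
        if len(merged)
        else pd.Series([], dtype=str)
    )
    rows: List[dict] = []
    for contig in sorted(genome):
        seq = genome[contig]
        L = len(seq)
        is_c = np.frombuffer(seq.encode(), dtype=np.uint8)
        cg = ((is_c == ord("C")) | (is_c == ord("G"))).astype(np.int64)
        cg_cum = np.concatenate([[0], np.cumsum(cg)])
        sub = merged[merged["contig"] == contig].sort_values("pos")
        positions = sub["pos"].to_numpy()
        categories = sub["category"].to_numpy()
        for size in range(win_min, win_max + 1, size_step):
            step = stride if stride is not None else max(1, size // 2)
            for start in range(0, max(1, L - size + 1), step):
                end = start + size
                if end > L:
                    break
                c_content = (cg_cum[end] - cg_cum[start]) / size
                if c_content < min_c_content:
                    continue
                lo = np.searchsorted(positions, start, side="left")
                hi = np.searchsorted(positions, end, side="left")
                cats = categories[lo:hi]
                if len(cats) == 0:
                    continue
                values, counts = np.unique(cats, return_counts=True)
                top = int(np.argmax(counts))
                rows.append(
                    {
                        "contig": contig,
                        "start": start,
                        "end": end,
                        "c_content": c_content,
                        "n_sites": len(cats),
                        "category": values[top],
                        "purity": counts[top] / len(cats),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "c_content", "n_sites", "category", "purity",
        ],
    )
    return df.sort_values(
        ["purity", "n_sites"], ascending=[False, False]
    ).reset_index(drop=True)
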