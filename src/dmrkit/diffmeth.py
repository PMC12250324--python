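"""Differential methylation calling from bisulfite call tables.

Implements the per-CpG and tiled (fixed-window) differential tests used in
RRBS comparisons of a control against a treated group: read counts are pooled
within each group, each CpG (or tile) is tested with a two-sided Fisher's
exact test on the 2x2 table (methylated/unmethylated x control/treated), and
p-values are corrected per comparison with Benjamini-Hochberg.  The
methylation difference is reported in percent points (treated - control).

A CpG enters the test only if its coverage reaches ``min_coverage`` in every
sample of both groups; defaults (coverage >= 10, q < 0.01, |diff| >= 25) are
the standard RRBS filter set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

CALL_COLUMNS = ["chrom", "pos", "strand", "coverage", "n_meth"]

#: relative slack used when summing tail probabilities, the convention shared
#: by R's fisher.test: tables with pmf <= pmf(observed) * (1 + 1e-7) count
#: toward the two-sided p-value.
_FISHER_GAMMA = 1.0 + 1e-7


@dataclass
class MethylationCallSet:
    """Per-CpG methylation calls for one sample.

    ``calls`` holds one row per cytosine: chrom, pos (1-based), strand,
    coverage (total reads) and n_meth (methylated reads).
    """

    calls: pd.DataFrame
    sample: str
    condition: str

    def __post_init__(self) -> None:
        df = self.calls
        missing = [c for c in CALL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"call table missing columns: {missing}")
        if (df["n_meth"] > df["coverage"]).any() or (df["n_meth"] < 0).any():
            raise ValueError("n_meth must satisfy 0 <= n_meth <= coverage")
        dup = df.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos, strand) records in call table")

    def destranded(self) -> "MethylationCallSet":
        """Merge +/- strand counts of each CpG dinucleotide onto the + strand.

        The G of a CpG sits one base downstream of the C, so minus-strand
        records at position p are folded onto position p - 1.
        """
        df = self.calls.copy()
        minus = df["strand"] == "-"
        df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
        merged = (
            df.groupby(["chrom", "pos"], as_index=False, sort=True)[["coverage", "n_meth"]]
            .sum()
        )
        merged["strand"] = "+"
        merged = merged[CALL_COLUMNS]
        return MethylationCallSet(merged, sample=self.sample, condition=self.condition)


def fisher_exact_pvalues(
    m_c: np.ndarray, u_c: np.ndarray, m_t: np.ndarray, u_t: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher exact p-values for a batch of 2x2 tables.

    Each table is [[m_c, u_c], [m_t, u_t]] (methylated / unmethylated reads in
    control and treated pools).  The p-value is the sum of hypergeometric
    probabilities of all tables, with the observed margins, that are no more
    probable than the observed one (relative slack 1 + 1e-7).

    Vectorised over tables sharing margins, which is what makes genome-scale
    calling affordable: distinct (N, K, n) triples are far fewer than CpGs.
    """
    m_c = np.asarray(m_c, dtype=np.int64)
    u_c = np.asarray(u_c, dtype=np.int64)
    m_t = np.asarray(m_t, dtype=np.int64)
    u_t = np.asarray(u_t, dtype=np.int64)
    if np.any(m_c < 0) or np.any(u_c < 0) or np.any(m_t < 0) or np.any(u_t < 0):
        raise ValueError("table entries must be non-negative")

    total = m_c + u_c + m_t + u_t  # N
    meth = m_c + m_t  # K: methylated margin
    ctrl = m_c + u_c  # n: control margin
    obs = m_c

    pvals = np.ones(total.shape[0], dtype=float)
    keys = np.stack([total, meth, ctrl], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(uniq.shape[0] + 1))
    for g in range(uniq.shape[0]):
        n_tot, k_meth, n_ctrl = uniq[g]
        idx = order[bounds[g] : bounds[g + 1]]
        k_lo = max(0, n_ctrl + k_meth - n_tot)
        k_hi = min(k_meth, n_ctrl)
        k = np.arange(k_lo, k_hi + 1)
        if len(k) == 1:
            continue  # degenerate margin: only one table, p = 1
        logpmf = (
            gammaln(k_meth + 1)
            - gammaln(k + 1)
            - gammaln(k_meth - k + 1)
            + gammaln(n_tot - k_meth + 1)
            - gammaln(n_ctrl - k + 1)
            - gammaln(n_tot - k_meth - n_ctrl + k + 1)
            - (gammaln(n_tot + 1) - gammaln(n_ctrl + 1) - gammaln(n_tot - n_ctrl + 1))
        )
        pmf = np.exp(logpmf)
        p_obs = pmf[obs[idx] - k_lo]
        mask = pmf[None, :] <= p_obs[:, None] * _FISHER_GAMMA
        pvals[idx] = np.minimum((pmf[None, :] * mask).sum(axis=1), 1.0)
    return pvals


def _pooled_counts(
    group: Sequence[MethylationCallSet], min_coverage: int, destrand: bool
) -> pd.DataFrame:
    """Pool counts across samples, keeping only positions covered at
    >= min_coverage in *every* sample of the group."""
    if not group:
        raise ValueError("empty sample group")
    frames = []
    for cs in group:
        cs = cs.destranded() if destrand else cs
        df = cs.calls.set_index(["chrom", "pos"])[["coverage", "n_meth"]]
        frames.append(df)
    cov = pd.concat([f["coverage"] for f in frames], axis=1, join="inner")
    meth = pd.concat([f["n_meth"] for f in frames], axis=1, join="inner")
    keep = (cov >= min_coverage).all(axis=1)
    pooled = pd.DataFrame(
        {"coverage": cov.loc[keep].sum(axis=1), "n_meth": meth.loc[keep].sum(axis=1)}
    )
    return pooled


def _finish_table(
    df: pd.DataFrame, kind: str, q_cut: float, diff_cut: float
) -> pd.DataFrame:
    df["kind"] = kind
    df["diff_meth"] = 100.0 * (
        df["m_t"] / df["cov_t"] - df["m_c"] / df["cov_c"]
    )
    df["p_value"] = fisher_exact_pvalues(
        df["m_c"].to_numpy(),
        (df["cov_c"] - df["m_c"]).to_numpy(),
        df["m_t"].to_numpy(),
        (df["cov_t"] - df["m_t"]).to_numpy(),
    )
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = (df["q_value"] < q_cut) & (df["diff_meth"].abs() >= diff_cut)
    cols = ["chrom", "start", "end", "kind", "diff_meth", "p_value", "q_value",
            "significant", "cov_c", "m_c", "cov_t", "m_t"]
    return df[cols].reset_index(drop=True)


def call_dmcs(
    control: Sequence[MethylationCallSet],
    treated: Sequence[MethylationCallSet],
    min_coverage: int = 10,
    q_cut: float = 0.01,
    diff_cut: float = 25.0,
    destrand: bool = True,
) -> pd.DataFrame:
    """Call differentially methylated CpGs between two sample groups.

    Returns one row per tested CpG (0-based half-open, width 1) with
    diff_meth in percent points, Fisher p, BH q and a ``significant`` flag;
    non-significant CpGs are retained.
    """
    ctrl = _pooled_counts(control, min_coverage, destrand)
    trt = _pooled_counts(treated, min_coverage, destrand)
    joined = ctrl.join(trt, how="inner", lsuffix="_c", rsuffix="_t")
    if joined.empty:
        raise ValueError(
            "no CpG position passes the coverage filter in both groups"
        )
    joined = joined.rename(
        columns={"coverage_c": "cov_c", "n_meth_c": "m_c",
                 "coverage_t": "cov_t", "n_meth_t": "m_t"}
    ).reset_index()
    joined["start"] = joined["pos"] - 1
    joined["end"] = joined["pos"]
    return _finish_table(joined, "cpg", q_cut, diff_cut)


def call_tiles(
    control: Sequence[MethylationCallSet],
    treated: Sequence[MethylationCallSet],
    window: int = 200,
    step: int = 200,
    min_coverage: int = 10,
    q_cut: float = 0.01,
    diff_cut: float = 25.0,
    destrand: bool = True,
) -> pd.DataFrame:
    """Call differentially methylated tiles (fixed windows on the 0-anchored
    grid).  Counts of eligible CpGs are summed per tile per group before the
    same Fisher + BH procedure as :func:`call_dmcs`; tiles with no eligible
    CpG are skipped.
    """
    if step != window:
        warnings.warn(
            "window != step produces overlapping tiles; multiplicity of "
            "tested regions changes accordingly",
            stacklevel=2,
        )
    ctrl = _pooled_counts(control, min_coverage, destrand)
    trt = _pooled_counts(treated, min_coverage, destrand)
    joined = ctrl.join(trt, how="inner", lsuffix="_c", rsuffix="_t")
    if joined.empty:
        raise ValueError(
            "no CpG position passes the coverage filter in both groups"
        )
    joined = joined.reset_index()
    pos0 = joined["pos"] - 1

    pieces = []
    n_offsets = max(1, -(-window // step))  # windows covering a position
    for i in range(n_offsets):
        tile = (pos0 // step - i) * step
        ok = (tile >= 0) & (pos0 < tile + window)
        part = joined.loc[ok].copy()
        part["start"] = tile[ok]
        pieces.append(part)
    stacked = pd.concat(pieces, ignore_index=True)
    agg = stacked.groupby(["chrom", "start"], as_index=False).agg(
        cov_c=("coverage_c", "sum"),
        m_c=("n_meth_c", "sum"),
        cov_t=("coverage_t", "sum"),
        m_t=("n_meth_t", "sum"),
    )
    agg["end"] = agg["start"] + window
    return _finish_table(agg, "tile", q_cut, diff_cut)


def global_shift_test(
    rates_a: Iterable[float], rates_b: Iterable[float]
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test for a global methylation shift.

    ``rates_a``/``rates_b`` are per-CpG methylation fractions matched by
    position.  Zero differences are dropped (Wilcoxon convention); fewer than
    5 non-zero pairs yields p = 1 with a warning.
    """
    a = np.asarray(list(rates_a), dtype=float)
    b = np.asarray(list(rates_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("rate vectors must be matched pairs of equal length")
    nonzero = int(np.sum(a != b))
    if nonzero < 5:
        warnings.warn(
            f"only {nonzero} non-zero pairs; signed-rank test not informative",
            stacklevel=2,
        )
        return float("nan"), 1.0
    stat, p = wilcoxon(b, a, zero_method="wilcox", alternative="two-sided")
    return float(stat), float(p)


def chromosome_distribution(
    dmcs: pd.DataFrame, q_cut: float = 0.01, min_diff: float = 5.0
) -> pd.DataFrame:
    """Per-chromosome distribution of hyper- and hypomethylated DMCs.

    Uses the relaxed effect-size threshold (default 5 points) appropriate for
    genome-wide distribution summaries, not the DMC calling threshold.  Each
    returned percentage column sums to 100 over chromosomes.
    """
    passing = dmcs[(dmcs["q_value"] < q_cut) & (dmcs["diff_meth"].abs() >= min_diff)]
    if passing.empty:
        warnings.warn("no DMC passes the distribution thresholds", stacklevel=2)
        return pd.DataFrame(columns=["hyper_pct", "hypo_pct"])
    hyper = passing[passing["diff_meth"] > 0].groupby("chrom").size()
    hypo = passing[passing["diff_meth"] < 0].groupby("chrom").size()
    out = pd.DataFrame({"hyper": hyper, "hypo": hypo}).fillna(0).astype(int)
    out["hyper_pct"] = 100.0 * out["hyper"] / max(out["hyper"].sum(), 1)
    out["hypo_pct"] = 100.0 * out["hypo"] / max(out["hypo"].sum(), 1)
    return out.sort_index()
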