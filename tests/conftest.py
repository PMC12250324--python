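"""Shared fixtures and independent oracles.

The oracles here re-derive expected values by brute force (exact integer
enumeration, all-pairs interval checks, O(n^3) clustering) and are kept free
of any dmrkit internals so they can referee the implementation.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import dmrkit as dk

# relative slack of the classical two-sided Fisher convention, as an exact
# integer ratio so the oracle stays in integer arithmetic
_SLACK_NUM, _SLACK_DEN = 10_000_001, 10_000_000


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact integer weights; a table counts toward the p-value when its weight
    w_k satisfies w_k * 1e7 <= w_obs * (1e7 + 1).
    """
    n_tot = a + b + c + d
    k_meth = a + c
    n_ctrl = a + b
    lo = max(0, n_ctrl + k_meth - n_tot)
    hi = min(k_meth, n_ctrl)
    w_obs = comb(k_meth, a) * comb(n_tot - k_meth, n_ctrl - a)
    num = 0
    for k in range(lo, hi + 1):
        w = comb(k_meth, k) * comb(n_tot - k_meth, n_ctrl - k)
        if w * _SLACK_DEN <= w_obs * _SLACK_NUM:
            num += w
    return num / comb(n_tot, n_ctrl)


def allpairs_overlap(queries: pd.DataFrame, track: pd.DataFrame) -> list[bool]:
    """O(n*m) any-overlap (>=1 bp, half-open) membership check."""
    out = []
    for _, q in queries.iterrows():
        hit = False
        for _, t in track.iterrows():
            if q["chrom"] == t["chrom"] and q["start"] < t["end"] and t["start"] < q["end"]:
                hit = True
                break
        out.append(hit)
    return out


def complete_linkage_cophenetic(X: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix from a brute-force O(n^3) complete-linkage
    agglomeration over the rows of X."""
    n = len(X)
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] |= clusters.pop(b)
    return coph


def make_callset(rows, sample="s", condition="c") -> dk.MethylationCallSet:
    """rows: iterable of (chrom, pos, strand, coverage, n_meth)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "coverage", "n_meth"])
    return dk.MethylationCallSet(df, sample=sample, condition=condition)


@pytest.fixture(scope="session")
def small_layout() -> dk.GenomeLayout:
    cfg = dk.LayoutConfig(
        chromosomes=(("chr1", 300_000), ("chr21", 300_000)),
        n_cgis=15,
        spacing={"CGI": 10.0, "promoter": 20.0, "repeat": 40.0, "background": 50.0},
    )
    return dk.generate_layout(cfg, seed=42)


@pytest.fixture(scope="session")
def planted_study(small_layout):
    """A control-vs-one-treatment study with 20 planted +-40 regions."""
    effects = dk.plant_effects(small_layout, 20, (40.0, -40.0), seed=43, min_cpgs=5)
    callsets, truth = dk.generate_methylome(
        small_layout, effects, n_replicates=2, coverage_mean=30.0, seed=44
    )
    return callsets, truth


@pytest.fixture(scope="session")
def tf_matrix_small():
    return dk.generate_tf_matrix(
        n_promoters=12, n_samples=30, n_unique=24, n_hyper=5, n_hypo=3, seed=7
    )
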