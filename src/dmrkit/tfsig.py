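"""Transcription-factor cell-identity simulation.

Starting from a promoter-by-sample CAGE expression matrix (tags per feature)
with a designated reference sample, three synthetic expression profiles are
derived from the methylation direction of each promoter — the working
assumption being that promoter hypermethylation lowers and hypomethylation
raises expression:

* maximum effect - the row minimum (hyper) or maximum (hypo);
* medium effect  - reference -/+ (median - min)/4 resp. (max - median)/4;
* low effect     - the same with divisor 8.

The augmented matrix is z-scored per row, duplicate sample columns are
collapsed, and samples are clustered hierarchically (Euclidean distance,
complete linkage) to see which real cell types the perturbed profiles most
resemble.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

EFFECT_LEVELS = ("low", "medium", "max")


def _validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.isna().any().any():
        n = int(matrix.isna().any(axis=1).sum())
        warnings.warn(f"dropping {n} row(s) with missing values", stacklevel=3)
        matrix = matrix.dropna(axis=0)
    if (matrix < 0).any().any():
        raise ValueError("expression values must be non-negative")
    return matrix


def simulate_profiles(
    matrix: pd.DataFrame,
    directions: pd.Series | dict,
    reference_column: str,
) -> pd.DataFrame:
    """Build the low/medium/max synthetic profiles.

    ``directions`` maps promoter id -> 'hyper' | 'hypo' | 'none'.  Row
    statistics (min, median, max) are computed across the real sample
    columns only; results are clamped to [row min, row max].  Constant rows
    are a no-op at every level.
    """
    matrix = _validate_matrix(matrix)
    if reference_column not in matrix.columns:
        raise ValueError(f"reference column {reference_column!r} absent from matrix")
    dirs = pd.Series(directions).reindex(matrix.index).fillna("none")
    bad = ~dirs.isin(["hyper", "hypo", "none"])
    if bad.any():
        raise ValueError(f"invalid directions: {sorted(dirs[bad].unique())}")

    v = matrix[reference_column].to_numpy(dtype=float)
    m = matrix.min(axis=1).to_numpy(dtype=float)
    d = matrix.median(axis=1).to_numpy(dtype=float)
    big = matrix.max(axis=1).to_numpy(dtype=float)
    hyper = (dirs == "hyper").to_numpy()
    hypo = (dirs == "hypo").to_numpy()
    constant = m == big
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s): simulation is a no-op there",
            stacklevel=2,
        )

    out = {}
    for level, divisor in (("low", 8.0), ("medium", 4.0)):
        vals = v.copy()
        vals[hyper] = v[hyper] - (d[hyper] - m[hyper]) / divisor
        vals[hypo] = v[hypo] + (big[hypo] - d[hypo]) / divisor
        out[level] = np.clip(vals, m, big)
    vals = v.copy()
    vals[hyper] = m[hyper]
    vals[hypo] = big[hypo]
    out["max"] = vals
    return pd.DataFrame(out, index=matrix.index)[list(EFFECT_LEVELS)]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row over all columns (population SD, divide by n).

    Constant rows become all-zero with a warning.
    """
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant row(s) set to 0", stacklevel=2)
    sd[flat] = 1.0
    z = (vals - mean) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def dedup_samples(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse columns with identical value vectors.

    The lexicographically first sample id of each duplicate group survives.
    Returns the reduced matrix (original column order among survivors) and a
    report of dropped ids with the id they duplicated.
    """
    groups: dict[tuple, list[str]] = {}
    for col in matrix.columns:
        groups.setdefault(tuple(matrix[col].to_numpy().tolist()), []).append(col)
    keep = set()
    dropped = []
    for cols in groups.values():
        first = min(cols)
        keep.add(first)
        for c in cols:
            if c != first:
                dropped.append(dict(dropped=c, kept=first))
    reduced = matrix[[c for c in matrix.columns if c in keep]]
    report = pd.DataFrame(dropped, columns=["dropped", "kept"]).sort_values(
        "dropped"
    ).reset_index(drop=True) if dropped else pd.DataFrame(columns=["dropped", "kept"])
    return reduced, report


def cluster_samples(
    matrix: pd.DataFrame,
    synthetic_columns: Sequence[str] = (),
    k: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Complete-linkage hierarchical clustering of sample columns.

    Returns the scipy linkage matrix over the columns (Euclidean distance)
    and, for each synthetic column, the ``k`` nearest real samples by raw
    Euclidean distance plus the first real sample its cluster joins in the
    dendrogram.
    """
    if matrix.shape[1] < 3:
        raise ValueError("clustering needs at least 3 columns")
    cols = list(matrix.columns)
    X = matrix.to_numpy(dtype=float).T
    Z = linkage(X, method="complete", metric="euclidean")

    real = [c for c in cols if c not in set(synthetic_columns)]
    rows = []
    for syn in synthetic_columns:
        if syn not in matrix.columns:
            raise ValueError(f"synthetic column {syn!r} absent")
        sv = matrix[syn].to_numpy(dtype=float)
        dists = {
            c: float(np.linalg.norm(matrix[c].to_numpy(dtype=float) - sv))
            for c in real
        }
        nearest = sorted(dists, key=lambda c: (dists[c], c))[:k]
        first_real = _first_real_join(Z, cols, syn, set(real), dists)
        for rank, c in enumerate(nearest, start=1):
            rows.append(
                dict(profile=syn, rank=rank, sample=c, distance=dists[c],
                     first_joined=first_real)
            )
    return Z, pd.DataFrame(rows, columns=["profile", "rank", "sample", "distance", "first_joined"])


def _first_real_join(
    Z: np.ndarray,
    cols: list[str],
    syn: str,
    real: set[str],
    dists: dict[str, float],
) -> str | None:
    """Walk the dendrogram: at the first merge where the synthetic column's
    cluster gains a real member, report the closest real sample among the
    newly joined ones."""
    n = len(cols)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    syn_idx = cols.index(syn)
    cluster_of = syn_idx
    for step, row in enumerate(Z):
        a, b = int(row[0]), int(row[1])
        new = n + step
        members[new] = members.pop(a) | members.pop(b)
        if cluster_of in (a, b):
            cluster_of = new
            # before a real sample joins, the synthetic's cluster holds only
            # synthetic columns, so any real member here came from the partner
            joined_real = [cols[i] for i in members[new] if cols[i] in real]
            if joined_real:
                return min(joined_real, key=lambda c: (dists[c], c))
    return None
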