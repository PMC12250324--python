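"""Assembly of DMCs and significant tiles into fixed 200-bp DMRs.

A DMR here is a window of the 0-anchored genomic grid supported by
significant single-CpG calls (DMCs), by a significant tile, or by both.  The
provenance is recorded as an origin flag:

* ``C`` - supported by clustered DMCs only (kept when it holds at least
  ``min_dmcs`` DMCs, default 4);
* ``M`` - supported by a significant tile only;
* ``T`` - supported by both;
* ``N`` - DMC-only candidate failing the ``min_dmcs`` filter; audited and
  dropped, never emitted as a result.

Cross-treatment sharing uses equal window *and* equal direction, so hyper-
and hypomethylated overlaps are counted separately in the Venn summary.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

DMR_COLUMNS = ["chrom", "start", "end", "direction", "n_dmc", "diff_meth", "origin_flag"]


def _direction(diff: pd.Series) -> pd.Series:
    return pd.Series(np.where(diff >= 0, "hyper", "hypo"), index=diff.index)


def _significant(df: pd.DataFrame) -> pd.DataFrame:
    if "significant" in df.columns:
        return df[df["significant"].astype(bool)]
    return df


def assemble_dmrs(
    dmcs: pd.DataFrame,
    tiles: pd.DataFrame,
    window: int = 200,
    min_dmcs: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble significant DMCs and tiles into grid DMRs.

    Parameters
    ----------
    dmcs, tiles
        Output tables of :func:`dmrkit.diffmeth.call_dmcs` /
        :func:`~dmrkit.diffmeth.call_tiles` from the same comparison.  Rows
        flagged non-significant are ignored.
    window
        Grid width in bp; tiles must already sit on this grid.
    min_dmcs
        Minimum DMC support for a region backed by DMC clustering alone.

    Returns
    -------
    (dmrs, audit)
        ``dmrs`` has one row per emitted region (flags C/M/T only).
        ``audit`` records dropped DMC-only candidates (flag N) and windows
        where the tile and DMC effect estimates disagreed in sign
        (flag ``conflict``; the tile sign wins in the emitted region).
    """
    dmcs = _significant(dmcs)
    tiles = _significant(tiles)
    if not tiles.empty:
        off_grid = (tiles["start"] % window != 0) | (
            tiles["end"] - tiles["start"] != window
        )
        if off_grid.any():
            raise ValueError("tiles are not on the requested grid")

    if dmcs.empty:
        dmc_win = pd.DataFrame(columns=["chrom", "start", "n_dmc", "dmc_diff"])
    else:
        tmp = dmcs.copy()
        tmp["win"] = (tmp["start"] // window) * window
        dmc_win = tmp.groupby(["chrom", "win"], as_index=False).agg(
            n_dmc=("diff_meth", "size"), dmc_diff=("diff_meth", "mean")
        )
        dmc_win = dmc_win.rename(columns={"win": "start"})

    tile_win = tiles[["chrom", "start", "diff_meth"]].rename(
        columns={"diff_meth": "tile_diff"}
    )

    merged = dmc_win.merge(tile_win, on=["chrom", "start"], how="outer")
    for col in ("start", "n_dmc", "dmc_diff", "tile_diff"):
        merged[col] = pd.to_numeric(merged[col])
    merged["n_dmc"] = merged["n_dmc"].fillna(0).astype(int)

    has_dmc = merged["n_dmc"] > 0
    has_tile = merged["tile_diff"].notna()
    flag = np.where(
        has_dmc & has_tile, "T",
        np.where(has_tile, "M", np.where(merged["n_dmc"] >= min_dmcs, "C", "N")),
    )
    merged["origin_flag"] = flag
    merged["diff_meth"] = merged["tile_diff"].where(has_tile, merged["dmc_diff"])
    merged["direction"] = _direction(merged["diff_meth"])
    merged["end"] = merged["start"] + window

    conflict = (
        has_dmc
        & has_tile
        & (np.sign(merged["tile_diff"]) != np.sign(merged["dmc_diff"]))
    )
    audit_rows = []
    dropped = merged[merged["origin_flag"] == "N"]
    for _, r in dropped.iterrows():
        audit_rows.append(
            dict(chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
                 flag="N", n_dmc=int(r["n_dmc"]), detail="dmc support below minimum")
        )
    if conflict.any():
        warnings.warn(
            f"{int(conflict.sum())} window(s) with opposite DMC/tile effect "
            "signs; tile sign kept",
            stacklevel=2,
        )
        for _, r in merged[conflict].iterrows():
            audit_rows.append(
                dict(chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
                     flag="conflict", n_dmc=int(r["n_dmc"]),
                     detail="tile and DMC signs disagree; tile sign kept")
            )
    audit = pd.DataFrame(audit_rows, columns=["chrom", "start", "end", "flag", "n_dmc", "detail"])

    out = merged[merged["origin_flag"] != "N"][DMR_COLUMNS].copy()
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out, audit


def flag_shared(
    dmr_sets: Mapping[str, pd.DataFrame]
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Annotate each treatment's DMRs with cross-treatment sharing flags and
    build the Venn membership table.

    Two DMRs are shared iff they occupy the same grid window with the same
    direction.  The Venn table counts windows per exact membership
    combination, split into all / hyper / hypo.
    """
    keysets: dict[str, set] = {}
    for name, df in dmr_sets.items():
        if df.duplicated(subset=["chrom", "start"]).any():
            raise ValueError(f"duplicated windows within DMR set '{name}'")
        keysets[name] = set(zip(df["chrom"], df["start"], df["direction"]))

    annotated = {}
    for name, df in dmr_sets.items():
        out = df.copy()
        keys = list(zip(df["chrom"], df["start"], df["direction"]))
        for other, kset in keysets.items():
            if other == name:
                continue
            out[f"shared_{other}"] = [k in kset for k in keys]
        annotated[name] = out

    names = sorted(keysets)
    all_keys = set().union(*keysets.values()) if keysets else set()
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            member = set(combo)
            count = count_hyper = count_hypo = 0
            for key in all_keys:
                present = {n for n in names if key in keysets[n]}
                if present == member:
                    count += 1
                    if key[2] == "hyper":
                        count_hyper += 1
                    else:
                        count_hypo += 1
            rows.append(
                dict(members="&".join(combo), n_sets=r, all=count,
                     hyper=count_hyper, hypo=count_hypo)
            )
    venn = pd.DataFrame(rows)
    return annotated, venn


def hypo_fraction(dmrs: pd.DataFrame) -> float:
    """Percentage of hypomethylated DMRs in a set."""
    if dmrs.empty:
        raise ValueError("hypo_fraction is undefined for an empty DMR set")
    return 100.0 * float((dmrs["direction"] == "hypo").sum()) / len(dmrs)
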