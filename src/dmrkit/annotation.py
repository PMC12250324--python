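"""Regulatory annotation of DMRs.

Builds promoter and CpG-island-shore tracks from primary annotation, overlaps
DMRs against arbitrary interval tracks (any-overlap >= 1 bp, half-open
coordinates), maps DMRs to genes via promoters (with nearest-TSS fallback for
enhancer-like cCRE hits), and ranks promoter DMRs by methylation difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

GENE_COLUMNS = ["chrom", "tss", "strand", "symbol", "gene_type"]


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (0-based half-open)."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end [, strand, label]
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"track '{self.name}' missing column {col}")
        if not df.empty and (df["start"] >= df["end"]).any():
            raise ValueError(f"track '{self.name}' has empty or inverted intervals")
        self.intervals = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    def tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            sub = self.intervals[self.intervals["chrom"] == chrom]
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), i) for i, (s, e) in enumerate(zip(sub["start"], sub["end"]))
            )
        return self._trees[chrom]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.tree(chrom).overlap(start, end))


def make_promoters(
    genes: pd.DataFrame,
    up: int = 1000,
    down: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> AnnotationTrack:
    """Strand-aware promoter windows around each TSS.

    On the + strand the window is [TSS - up, TSS + down); on the - strand the
    upstream/downstream roles are mirrored.  Windows are clipped to the
    chromosome; genes whose TSS lies outside the chromosome are rejected.
    """
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    df = genes.copy()
    if chrom_sizes is not None:
        sizes = df["chrom"].map(chrom_sizes)
        bad = sizes.isna() | (df["tss"] < 0) | (df["tss"] >= sizes)
        if bad.any():
            warnings.warn(
                f"rejected {int(bad.sum())} gene(s) with TSS outside the chromosome",
                stacklevel=2,
            )
            df = df[~bad]
    plus = df["strand"] != "-"
    start = np.where(plus, df["tss"] - up, df["tss"] - down)
    end = np.where(plus, df["tss"] + down, df["tss"] + up)
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": start, "end": end,
         "strand": df["strand"], "label": df["symbol"]}
    )
    out["start"] = out["start"].clip(lower=0)
    if chrom_sizes is not None:
        out["end"] = np.minimum(out["end"], out["chrom"].map(chrom_sizes))
    out = out[out["start"] < out["end"]]
    return AnnotationTrack("promoter", out.reset_index(drop=True))


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_cgi_shores(
    cgis: AnnotationTrack | pd.DataFrame,
    shore: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> AnnotationTrack:
    """Flanking shores (default 2 kb each side) of merged CpG islands.

    Shores are truncated where they would run into a neighbouring island, and
    clipped to chromosome bounds.
    """
    df = cgis.intervals if isinstance(cgis, AnnotationTrack) else cgis
    merged = merge_intervals(df)
    rows = []
    for chrom, sub in merged.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        limit = chrom_sizes.get(chrom) if chrom_sizes else None
        for i in range(len(starts)):
            left_lo = max(0, starts[i] - shore, ends[i - 1] if i > 0 else 0)
            if left_lo < starts[i]:
                rows.append((chrom, left_lo, starts[i]))
            right_hi = ends[i] + shore
            if i + 1 < len(starts):
                right_hi = min(right_hi, starts[i + 1])
            if limit is not None:
                right_hi = min(right_hi, limit)
            if ends[i] < right_hi:
                rows.append((chrom, ends[i], right_hi))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return AnnotationTrack("cgi_shore", out)


def annotate_dmrs(
    dmrs: pd.DataFrame, tracks: Sequence[AnnotationTrack]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap DMRs against annotation tracks.

    Returns the per-DMR boolean feature matrix (one column per track) and a
    summary table with total and per-direction counts and percentages; a DMR
    may count toward several tracks.
    """
    matrix = pd.DataFrame(index=dmrs.index)
    for track in tracks:
        if track.intervals.empty:
            warnings.warn(f"track '{track.name}' has no intervals", stacklevel=2)
            matrix[track.name] = False
            continue
        matrix[track.name] = [
            track.overlaps(c, int(s), int(e))
            for c, s, e in zip(dmrs["chrom"], dmrs["start"], dmrs["end"])
        ]
    n_tot = len(dmrs)
    hyper_mask = (dmrs["direction"] == "hyper") if "direction" in dmrs else pd.Series(False, index=dmrs.index)
    hypo_mask = (dmrs["direction"] == "hypo") if "direction" in dmrs else pd.Series(False, index=dmrs.index)
    n_hyper = int(hyper_mask.sum())
    n_hypo = int(hypo_mask.sum())
    rows = []
    for track in tracks:
        hit = matrix[track.name]
        tot = int(hit.sum())
        hyp = int((hit & hyper_mask).sum())
        hpo = int((hit & hypo_mask).sum())
        rows.append(
            dict(
                track=track.name,
                tot=tot,
                pct_tot=100.0 * tot / n_tot if n_tot else 0.0,
                hyper=hyp,
                pct_hyper=100.0 * hyp / n_hyper if n_hyper else 0.0,
                hypo=hpo,
                pct_hypo=100.0 * hpo / n_hypo if n_hypo else 0.0,
            )
        )
    return matrix, pd.DataFrame(rows)


def assign_genes(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    promoters: AnnotationTrack | None = None,
    ccres: AnnotationTrack | None = None,
    max_dist: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Map DMRs to genes and tabulate gene-type proportions.

    A DMR overlapping a promoter is assigned to that promoter's gene(s);
    a DMR overlapping a cCRE but no promoter is assigned to the nearest TSS
    within ``max_dist`` bp.  Returns the deduplicated gene table, the
    gene-type proportion table (percent of unique genes, summing to 100),
    and the count of cCRE DMRs left unassigned.
    """
    if promoters is None:
        promoters = make_promoters(genes)
    prom = promoters.intervals
    assigned: dict[str, str] = {}
    unassigned = 0
    tss_by_chrom = {
        chrom: sub.sort_values("tss") for chrom, sub in genes.groupby("chrom")
    }
    for _, d in dmrs.iterrows():
        chrom, s, e = d["chrom"], int(d["start"]), int(d["end"])
        hits = promoters.tree(chrom).overlap(s, e)
        if hits:
            sub = prom[prom["chrom"] == chrom].reset_index(drop=True)
            for h in hits:
                sym = sub.iloc[h.data]["label"]
                assigned.setdefault(sym, "promoter")
        elif ccres is not None and ccres.overlaps(chrom, s, e):
            sub = tss_by_chrom.get(chrom)
            if sub is None or sub.empty:
                unassigned += 1
                continue
            mid = (s + e) // 2
            tss = sub["tss"].to_numpy()
            i = np.searchsorted(tss, mid)
            cand = [j for j in (i - 1, i) if 0 <= j < len(tss)]
            j = min(cand, key=lambda j: abs(int(tss[j]) - mid))
            if abs(int(tss[j]) - mid) <= max_dist:
                assigned.setdefault(sub.iloc[j]["symbol"], "ccre_nearest")
            else:
                unassigned += 1
    gene_rows = genes.drop_duplicates("symbol").set_index("symbol")
    out = pd.DataFrame(
        [
            dict(symbol=sym, gene_type=gene_rows.loc[sym, "gene_type"], via=via)
            for sym, via in sorted(assigned.items())
            if sym in gene_rows.index
        ],
        columns=["symbol", "gene_type", "via"],
    )
    if out.empty:
        props = pd.DataFrame(columns=["gene_type", "pct"])
    else:
        counts = out["gene_type"].value_counts()
        props = (100.0 * counts / counts.sum()).rename("pct").reset_index()
        props.columns = ["gene_type", "pct"]
    return out, props, unassigned


def rank_promoter_dmrs(
    dmrs_primary: pd.DataFrame,
    dmrs_other: pd.DataFrame,
    promoters: AnnotationTrack,
    direction: str,
    diff_range: tuple[float, float],
) -> pd.DataFrame:
    """Rank genes by promoter DMR methylation difference.

    Considers DMRs shared between the two treatments (same window, same
    direction), keeps those overlapping a promoter whose difference (from the
    primary treatment) lies in the closed interval ``diff_range``, and sorts
    by |diff_meth| descending with alphabetical tie-break on the gene symbol.
    One row per gene (largest |diff| kept).
    """
    lo, hi = diff_range
    if lo > hi:
        raise ValueError("diff_range must be (lo, hi) with lo <= hi")
    other_keys = set(zip(dmrs_other["chrom"], dmrs_other["start"], dmrs_other["direction"]))
    prom = promoters.intervals
    rows = []
    for _, d in dmrs_primary.iterrows():
        if d["direction"] != direction:
            continue
        if (d["chrom"], d["start"], d["direction"]) not in other_keys:
            continue
        diff = float(d["diff_meth"])
        if not (lo <= diff <= hi):
            continue
        hits = promoters.tree(d["chrom"]).overlap(int(d["start"]), int(d["end"]))
        sub = prom[prom["chrom"] == d["chrom"]].reset_index(drop=True)
        for h in hits:
            rows.append(
                dict(gene=sub.iloc[h.data]["label"], diff_meth=diff,
                     chrom=d["chrom"], start=int(d["start"]), end=int(d["end"]))
            )
    if not rows:
        return pd.DataFrame(columns=["gene", "diff_meth", "chrom", "start", "end"])
    out = pd.DataFrame(rows)
    out["absdiff"] = out["diff_meth"].abs()
    out = out.sort_values(["absdiff", "gene"], ascending=[False, True])
    out = out.drop_duplicates("gene", keep="first").drop(columns="absdiff")
    return out.reset_index(drop=True)
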