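"""Methylation analysis of repetitive elements.

Assigns DMCs to repeat families (Alu, MIR, L1, L2, microsatellites, simple
repeats, ...), compares genome-wide counts with a named chromosome subset,
measures the genomic proportion of each repeat class, and computes mean CpG
dinucleotide content per family from sequence.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import merge_intervals

REPEAT_COLUMNS = ["chrom", "start", "end", "name", "rep_class", "family"]

#: families singled out in per-family distribution summaries; everything else
#: is aggregated as "Other RE" (with the sub-breakdown retained).
DEFAULT_FAMILIES = ("Alu", "MIR", "L1", "L2", "Microsatellite", "Simple_repeat")


def assign_repeats(dmcs: pd.DataFrame, repeats: pd.DataFrame) -> pd.Series:
    """Family label of the repeat containing each DMC, or NA.

    A DMC inside nested/overlapping repeats is assigned to the smallest
    containing interval (most specific element); ties go to the first in
    sorted order.
    """
    for col in REPEAT_COLUMNS[:3] + ["family"]:
        if col not in repeats.columns:
            raise ValueError(f"repeat table missing column {col}")
    reps = repeats.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out = pd.Series(pd.NA, index=dmcs.index, dtype="object")
    for chrom, sub in reps.groupby("chrom"):
        mask = dmcs["chrom"] == chrom
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        fams = sub["family"].to_numpy()
        lengths = ends - starts
        pos = dmcs.loc[mask, "start"].to_numpy()
        labels = []
        for p in pos:
            # candidate repeats starting at or before p
            hi = np.searchsorted(starts, p, side="right")
            cover = np.nonzero(ends[:hi] > p)[0]
            if len(cover) == 0:
                labels.append(pd.NA)
            else:
                best = cover[np.argmin(lengths[cover], )]
                labels.append(fams[best])
        out.loc[mask] = labels
    return out


def annotate_dmcs_repeats(
    dmc_sets: Mapping[str, pd.DataFrame],
    repeats: pd.DataFrame,
    subset_chrom: str | None = None,
) -> tuple[dict[str, pd.Series], pd.DataFrame]:
    """Count DMCs inside repetitive elements, overall and on one chromosome.

    ``dmc_sets`` maps a stratum label (e.g. ``"IND50 hyper"``) to a table of
    significant DMCs.  Returns the per-stratum family assignment and a
    summary table with rows: all DMCs, DMCs in repeats, and (when
    ``subset_chrom`` is given) the same restricted to that chromosome.
    """
    assignments: dict[str, pd.Series] = {}
    rows: dict[str, dict[str, int]] = {}
    for label, dmcs in dmc_sets.items():
        fam = assign_repeats(dmcs, repeats)
        assignments[label] = fam
        col = {
            "All DMC": len(dmcs),
            "All DMC in RE": int(fam.notna().sum()),
        }
        if subset_chrom is not None:
            on = dmcs["chrom"] == subset_chrom
            col[f"{subset_chrom} DMC"] = int(on.sum())
            col[f"{subset_chrom} DMC in RE"] = int((fam.notna() & on).sum())
        rows[label] = col
    summary = pd.DataFrame(rows)
    return assignments, summary


def repeat_proportions(
    repeats: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    chrom: str | None = None,
    by: str = "family",
) -> pd.DataFrame:
    """Percent of genomic bp covered by each repeat family (or class).

    Same-group intervals are unioned before measuring; the denominator is the
    total bp of the scope (whole genome or one chromosome).
    """
    if by not in ("family", "rep_class"):
        raise ValueError("by must be 'family' or 'rep_class'")
    scope = repeats if chrom is None else repeats[repeats["chrom"] == chrom]
    if chrom is None:
        total_bp = sum(chrom_sizes.values())
    else:
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        total_bp = chrom_sizes[chrom]
    if total_bp <= 0:
        raise ValueError("empty scope")
    rows = []
    for group, sub in scope.groupby(by, sort=True):
        merged = merge_intervals(sub[["chrom", "start", "end"]])
        bp = int((merged["end"] - merged["start"]).sum())
        rows.append(dict(group=group, bp=bp, pct=100.0 * bp / total_bp))
    merged_all = merge_intervals(scope[["chrom", "start", "end"]]) if not scope.empty else pd.DataFrame(columns=["start", "end"])
    all_bp = int((merged_all["end"] - merged_all["start"]).sum()) if not merged_all.empty else 0
    rows.append(dict(group="All repeats", bp=all_bp, pct=100.0 * all_bp / total_bp))
    out = pd.DataFrame(rows, columns=["group", "bp", "pct"])
    return out.rename(columns={"group": by})


def cpg_content(families: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Mean CpG dinucleotide percentage per repeat family.

    Per sequence the value is 100 * (# "CG" dinucleotides) / (L - 1), with L
    the sequence length; positions involving ambiguous bases are skipped in
    both numerator and denominator.  The family value is the mean over its
    sequences; sequences shorter than 2 bp are excluded with a warning.
    """
    rows = []
    for family, seqs in sorted(families.items()):
        vals = []
        for seq in seqs:
            s = str(seq).upper()
            if len(s) < 2:
                warnings.warn(
                    f"skipping sequence of length {len(s)} in family {family}",
                    stacklevel=2,
                )
                continue
            valid = np.frombuffer(s.encode(), dtype="S1")
            ok = np.isin(valid, [b"A", b"C", b"G", b"T"])
            pair_ok = ok[:-1] & ok[1:]
            denom = int(pair_ok.sum())
            if denom == 0:
                warnings.warn(
                    f"sequence with no unambiguous dinucleotide in family {family}",
                    stacklevel=2,
                )
                continue
            cg = (valid[:-1] == b"C") & (valid[1:] == b"G") & pair_ok
            vals.append(100.0 * int(cg.sum()) / denom)
        rows.append(
            dict(family=family, mean_cpg_pct=float(np.mean(vals)) if vals else np.nan,
                 n_seqs=len(vals))
        )
    return pd.DataFrame(rows)


def re_distribution(
    dmc_sets: Mapping[str, pd.DataFrame],
    repeats: pd.DataFrame,
    chrom: str | None = None,
    families: Sequence[str] = DEFAULT_FAMILIES,
    other_label: str = "Other RE",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of repeat-overlapping DMCs across repeat families.

    For each stratum (typically direction x treatment, optionally restricted
    to one chromosome) returns the percentage of repeat DMCs per named
    family; families outside ``families`` are pooled as ``other_label`` with
    the sub-breakdown returned separately.  Percentages sum to 100 within
    each stratum.
    """
    main_rows: dict[str, pd.Series] = {}
    other_rows: dict[str, pd.Series] = {}
    for label, dmcs in dmc_sets.items():
        sub = dmcs if chrom is None else dmcs[dmcs["chrom"] == chrom]
        fam = assign_repeats(sub, repeats).dropna()
        if fam.empty:
            warnings.warn(f"stratum '{label}' has no repeat-overlapping DMC", stacklevel=2)
            main_rows[label] = pd.Series(dtype=float)
            continue
        counts = fam.value_counts()
        named = counts.reindex(families, fill_value=0)
        other = counts[~counts.index.isin(families)]
        total = counts.sum()
        pct = 100.0 * named / total
        pct[other_label] = 100.0 * other.sum() / total
        main_rows[label] = pct
        if other.sum():
            other_rows[label] = 100.0 * other / other.sum()
    main = pd.DataFrame(main_rows).fillna(0.0)
    sub_other = pd.DataFrame(other_rows).fillna(0.0)
    return main, sub_other
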