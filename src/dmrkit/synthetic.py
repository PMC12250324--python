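"""Synthetic RRBS study generator with known ground truth.

Builds every input the pipeline consumes: a small genome layout with CpG
positions stratified by compartment (CpG islands are CpG-dense and lowly
methylated, repeats CpG-moderate and highly methylated, background sparse and
intermediate), per-sample methylation call tables with planted hyper/hypo
effects per treatment, matching annotation BED tracks, a repeat catalogue
with sequences, and a promoter-by-sample CAGE-like expression matrix with a
designated reference column and deliberate duplicate columns.

Defaults mirror the study design this pipeline targets: an untreated control
against three treatment doses (IND10/IND50/IND100), two replicates per
condition, negative-binomial coverage around 30x, planted effects of +-40
percent points detectable under the q < 0.01, |diff| >= 25 filter set.
Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffmeth import MethylationCallSet

TREATMENTS = ("IND10", "IND50", "IND100")
CONTROL = "CTRL"

#: beta(a, b) baselines per compartment kind: CGIs hover near 10%
#: methylation, repeats near 80%, open background near 50%.
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "CGI": (1.0, 9.0),
    "promoter": (1.5, 8.5),
    "repeat": (8.0, 2.0),
    "background": (5.0, 5.0),
}

#: mean gap in bp between consecutive CpGs per compartment kind.
DEFAULT_SPACING: dict[str, float] = {
    "CGI": 10.0,
    "promoter": 20.0,
    "repeat": 40.0,
    "background": 100.0,
}

DEFAULT_REPEAT_FAMILIES: dict[str, tuple[str, int, int]] = {
    # family -> (class, copies per chromosome, element length)
    "Alu": ("SINE", 60, 300),
    "MIR": ("SINE", 25, 260),
    "L1": ("LINE", 20, 1500),
    "L2": ("LINE", 15, 800),
    "Microsatellite": ("Satellite", 10, 200),
    "Simple_repeat": ("Simple_repeat", 15, 150),
    "LTR": ("LTR", 10, 600),
    "rRNA": ("rRNA", 3, 400),
}


@dataclass
class LayoutConfig:
    chromosomes: Sequence[tuple[str, int]] = (("chr1", 1_000_000), ("chr21", 1_000_000))
    n_cgis: int = 40                      # per chromosome
    cgi_length: int = 1_000
    gene_fraction_in_cgi: float = 0.7     # genes whose TSS sits in a CGI
    n_background_genes: int = 10          # extra genes per chromosome
    repeat_families: Mapping[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_FAMILIES)
    )
    spacing: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SPACING))
    gene_types: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.60, "lncRNA": 0.30, "miRNA": 0.05, "misc_RNA": 0.05,
        }
    )


@dataclass
class GenomeLayout:
    """Synthetic genome: chromosome sizes, CpG positions (0-based, C of the
    CpG on the + strand), a complete compartment partition, genes and
    annotation tracks."""

    chromosomes: list[tuple[str, int]]
    cpg_positions: dict[str, np.ndarray]
    compartments: pd.DataFrame           # chrom, start, end, kind, family
    genes: pd.DataFrame                  # chrom, tss, strand, symbol, gene_type
    tracks: dict[str, pd.DataFrame]      # name -> BED-like frame

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_cpgs(self) -> int:
        return int(sum(len(v) for v in self.cpg_positions.values()))


@dataclass
class EffectSpec:
    """A planted methylation effect: ``delta`` percent points applied to all
    CpGs in [start, end) of ``chrom`` for the listed treatments."""

    chrom: str
    start: int
    end: int
    delta: float
    treatments: tuple[str, ...]

    def __post_init__(self) -> None:
        if abs(self.delta) > 100:
            raise ValueError("|delta| must be <= 100 percent points")
        if self.start >= self.end:
            raise ValueError("empty effect interval")


def generate_layout(config: LayoutConfig | None = None, seed: int = 0) -> GenomeLayout:
    """Lay out CGIs, repeats, genes and CpG positions on each chromosome.

    Features are placed without overlap; CpG positions are drawn with
    geometric gaps whose mean is the per-compartment spacing, so CGI CpG
    density exceeds background density by construction.  Deterministic for a
    fixed seed.
    """
    config = config or LayoutConfig()
    if len(config.chromosomes) < 2:
        raise ValueError("need at least 2 chromosomes (one plays the subset role)")
    for kind, sp in config.spacing.items():
        if sp < 1.0:
            raise ValueError(
                f"spacing {sp} for {kind!r} implies >1 CpG per bp; positions would collide"
            )
    rng = np.random.default_rng(seed)

    comp_rows = []
    gene_rows = []
    track_rows: dict[str, list] = {
        "cgi": [], "repeats": [], "tss": [], "cage_tss": [], "ccre": [],
        "dhs": [], "ctcf": [], "h3k4me1": [], "h3k4me3": [], "h3k9me3": [],
        "h3k36me3": [],
    }
    gene_counter = 0
    type_names = list(config.gene_types)
    type_probs = np.array([config.gene_types[t] for t in type_names], dtype=float)
    type_probs = type_probs / type_probs.sum()

    for chrom, length in config.chromosomes:
        features: list[tuple[str, str, int]] = []  # (kind, family, length)
        features += [("CGI", "", config.cgi_length)] * config.n_cgis
        for fam, (cls, copies, flen) in config.repeat_families.items():
            features += [("repeat", fam, flen)] * copies
        total_feat = sum(f[2] for f in features)
        if total_feat > 0.7 * length:
            raise ValueError(
                f"features ({total_feat} bp) exceed 70% of chromosome {chrom} ({length} bp)"
            )
        order = rng.permutation(len(features))
        features = [features[i] for i in order]
        slack = length - total_feat
        gaps = rng.multinomial(slack, np.ones(len(features) + 1) / (len(features) + 1))

        pos = 0
        rep_counter = 0
        for (kind, fam, flen), gap in zip(features, gaps[:-1]):
            pos += int(gap)
            start, end = pos, pos + flen
            comp_rows.append((chrom, start, end, kind, fam))
            if kind == "CGI":
                track_rows["cgi"].append((chrom, start, end, "CGI", 0, "+"))
                if rng.random() < config.gene_fraction_in_cgi:
                    strand = "+" if rng.random() < 0.5 else "-"
                    tss = int(rng.integers(start, end))
                    gene_counter += 1
                    gtype = type_names[int(rng.choice(len(type_names), p=type_probs))]
                    gene_rows.append((chrom, tss, strand, f"GENE{gene_counter:04d}", gtype))
            else:
                cls = config.repeat_families[fam][0]
                rep_counter += 1
                track_rows["repeats"].append(
                    (chrom, start, end, f"{fam}_{chrom}_{rep_counter}", 0, "+", cls, fam)
                )
            pos = end
        # background genes
        for _ in range(config.n_background_genes):
            tss = int(rng.integers(0, length))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter += 1
            gtype = type_names[int(rng.choice(len(type_names), p=type_probs))]
            gene_rows.append((chrom, tss, strand, f"GENE{gene_counter:04d}", gtype))

    comp = pd.DataFrame(comp_rows, columns=["chrom", "start", "end", "kind", "family"])
    genes = pd.DataFrame(gene_rows, columns=["chrom", "tss", "strand", "symbol", "gene_type"])
    genes = genes.sort_values(["chrom", "tss"]).reset_index(drop=True)

    # complete the partition with background segments
    full_rows = []
    for chrom, length in config.chromosomes:
        sub = comp[comp["chrom"] == chrom].sort_values("start")
        cursor = 0
        for _, r in sub.iterrows():
            if r["start"] > cursor:
                full_rows.append((chrom, cursor, r["start"], "background", ""))
            full_rows.append((chrom, r["start"], r["end"], r["kind"], r["family"]))
            cursor = r["end"]
        if cursor < length:
            full_rows.append((chrom, cursor, length, "background", ""))
    partition = pd.DataFrame(full_rows, columns=["chrom", "start", "end", "kind", "family"])

    # CpG positions: geometric gaps within each segment
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom, length in config.chromosomes:
        sub = partition[partition["chrom"] == chrom]
        positions: list[int] = []
        for _, seg in sub.iterrows():
            spacing = config.spacing.get(seg["kind"], config.spacing["background"])
            p = int(seg["start"]) + int(rng.geometric(1.0 / spacing))
            while p < seg["end"] - 1:  # leave room for the G of the CpG
                positions.append(p)
                p += int(rng.geometric(1.0 / spacing)) + 1
        cpg_positions[chrom] = np.asarray(sorted(positions), dtype=np.int64)

    # accessory regulatory tracks around genes / in the open genome
    for _, g in genes.iterrows():
        chrom, tss, strand = g["chrom"], int(g["tss"]), g["strand"]
        length = dict(config.chromosomes)[chrom]
        track_rows["tss"].append((chrom, tss, tss + 1, g["symbol"], 0, strand))
        jitter = int(rng.integers(-20, 21))
        cage = min(max(tss + jitter, 0), length - 1)
        track_rows["cage_tss"].append((chrom, cage, cage + 1, f"p1@{g['symbol']}", 0, strand))
        pstart = max(0, tss - 300)
        pend = min(length, tss + 300)
        track_rows["ccre"].append((chrom, pstart, pend, "PLS", 0, "."))
        track_rows["h3k4me3"].append((chrom, max(0, tss - 500), min(length, tss + 500), ".", 0, "."))
        if rng.random() < 0.6:
            track_rows["dhs"].append((chrom, max(0, tss - 150), min(length, tss + 150), ".", 0, "."))
    for chrom, length in config.chromosomes:
        for _ in range(30):
            s = int(rng.integers(0, length - 2000))
            track_rows["ccre"].append((chrom, s, s + 350, "dELS", 0, "."))
            if rng.random() < 0.5:
                track_rows["h3k4me1"].append((chrom, s - 100 if s >= 100 else 0, s + 450, ".", 0, "."))
        for _ in range(15):
            s = int(rng.integers(0, length - 1000))
            track_rows["ctcf"].append((chrom, s, s + 300, ".", 0, "."))
        for name, n in (("h3k9me3", 8), ("h3k36me3", 8)):
            for _ in range(n):
                s = int(rng.integers(0, length - 3000))
                track_rows[name].append((chrom, s, s + 2000, ".", 0, "."))

    tracks = {}
    for name, rows in track_rows.items():
        cols = ["chrom", "start", "end", "name", "score", "strand"]
        if name == "repeats":
            cols = cols + ["rep_class", "family"]
        tracks[name] = (
            pd.DataFrame(rows, columns=cols)
            .sort_values(["chrom", "start"])
            .reset_index(drop=True)
        )

    return GenomeLayout(
        chromosomes=list(config.chromosomes),
        cpg_positions=cpg_positions,
        compartments=partition,
        genes=genes,
        tracks=tracks,
    )


def _compartment_kind(layout: GenomeLayout, chrom: str, pos: np.ndarray) -> np.ndarray:
    sub = layout.compartments[layout.compartments["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    kinds = sub["kind"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    return kinds[idx]


def generate_methylome(
    layout: GenomeLayout,
    effects: Sequence[EffectSpec] = (),
    n_replicates: int = 2,
    coverage_mean: float = 30.0,
    coverage_dispersion: float = 10.0,
    baselines: Mapping[str, tuple[float, float]] | None = None,
    treatments: Sequence[str] = TREATMENTS,
    seed: int = 0,
) -> tuple[dict[str, list[MethylationCallSet]], pd.DataFrame]:
    """Simulate per-sample methylation call tables with planted effects.

    The latent methylation fraction of each CpG is drawn once from its
    compartment's beta baseline and held fixed across replicates and
    conditions; treated conditions shift it by the planted delta (clamped to
    [0, 1]) inside affected regions.  Replicate noise is binomial sampling at
    negative-binomial coverage.  Returns the call sets per condition plus a
    BED6-style truth table (score = delta, name = affected treatments).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    baselines = dict(baselines or DEFAULT_BASELINES)
    for eff in effects:
        unknown = set(eff.treatments) - set(treatments)
        if unknown:
            raise ValueError(f"unknown treatment label(s) {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    nb_n = coverage_dispersion
    nb_p = coverage_dispersion / (coverage_dispersion + coverage_mean)

    conditions = [CONTROL, *treatments]
    callsets: dict[str, list[MethylationCallSet]] = {c: [] for c in conditions}
    chrom_frames: dict[str, dict] = {}

    for chrom, _length in layout.chromosomes:
        pos0 = layout.cpg_positions[chrom]
        kinds = _compartment_kind(layout, chrom, pos0)
        p_base = np.empty(len(pos0))
        for kind in np.unique(kinds):
            a, b = baselines.get(kind, baselines["background"])
            mask = kinds == kind
            p_base[mask] = rng.beta(a, b, size=int(mask.sum()))
        delta = {t: np.zeros(len(pos0)) for t in treatments}
        for eff in effects:
            if eff.chrom != chrom:
                continue
            inside = (pos0 >= eff.start) & (pos0 < eff.end)
            for t in eff.treatments:
                delta[t][inside] += eff.delta / 100.0
        chrom_frames[chrom] = dict(pos0=pos0, p_base=p_base, delta=delta)

    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            frames = []
            for chrom, _length in layout.chromosomes:
                info = chrom_frames[chrom]
                p = info["p_base"].copy()
                if cond != CONTROL:
                    p = np.clip(p + info["delta"][cond], 0.0, 1.0)
                cov = rng.negative_binomial(nb_n, nb_p, size=len(p))
                meth = rng.binomial(cov, p)
                frames.append(
                    pd.DataFrame(
                        {"chrom": chrom, "pos": info["pos0"] + 1, "strand": "+",
                         "coverage": cov, "n_meth": meth}
                    )
                )
            calls = pd.concat(frames, ignore_index=True)
            calls = calls[calls["coverage"] > 0].reset_index(drop=True)
            callsets[cond].append(
                MethylationCallSet(calls, sample=f"{cond}_rep{rep}", condition=cond)
            )

    truth = pd.DataFrame(
        [
            dict(chrom=e.chrom, start=e.start, end=e.end,
                 name="+".join(e.treatments), score=e.delta, strand="+")
            for e in effects
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    return callsets, truth


def plant_effects(
    layout: GenomeLayout,
    n_regions: int,
    delta: float | Sequence[float],
    treatments: Sequence[str] = TREATMENTS,
    window: int = 200,
    min_cpgs: int = 5,
    compartment: str = "background",
    seed: int = 0,
) -> list[EffectSpec]:
    """Choose grid windows with enough CpGs in the given compartment and
    plant effects there.

    ``delta`` may be a scalar or a sequence cycled over regions (e.g.
    ``(+40, -40)`` for alternating hyper/hypo effects).
    """
    rng = np.random.default_rng(seed)
    deltas = np.atleast_1d(np.asarray(delta, dtype=float))
    candidates = []
    comp = layout.compartments
    for chrom, length in layout.chromosomes:
        pos0 = layout.cpg_positions[chrom]
        kinds = _compartment_kind(layout, chrom, pos0)
        eligible_pos = pos0[kinds == compartment]
        wins, counts = np.unique(eligible_pos // window, return_counts=True)
        all_wins, all_counts = np.unique(pos0 // window, return_counts=True)
        total = dict(zip(all_wins, all_counts))
        for w, c in zip(wins, counts):
            # window must be purely this compartment's CpGs and dense enough
            if c >= min_cpgs and total[w] == c:
                candidates.append((chrom, int(w) * window))
    if len(candidates) < n_regions:
        raise ValueError(
            f"only {len(candidates)} candidate windows with >= {min_cpgs} CpGs; "
            f"cannot plant {n_regions} regions"
        )
    pick = rng.choice(len(candidates), size=n_regions, replace=False)
    effects = []
    for i, ci in enumerate(sorted(pick)):
        chrom, start = candidates[ci]
        effects.append(
            EffectSpec(chrom=chrom, start=start, end=start + window,
                       delta=float(deltas[i % len(deltas)]),
                       treatments=tuple(treatments))
        )
    return effects


def generate_tf_matrix(
    n_promoters: int = 23,
    n_samples: int = 889,
    n_unique: int = 592,
    reference_column: str = "Caco-2",
    n_hyper: int = 18,
    n_hypo: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """CAGE-like promoter-by-sample expression matrix with ground truth.

    Defaults mirror the study shape: 23 promoters profiled across 889
    samples of which 592 are unique (the rest are exact duplicate columns,
    exercising deduplication), one reference column, and a direction label
    (hyper/hypo/none) per promoter.  Values are non-negative tags-per-feature
    drawn log-normally with a per-promoter scale; the reference column is a
    genuine sample column.  Returns (matrix, directions).
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples for distinct min/median/max roles")
    if not (1 <= n_unique <= n_samples):
        raise ValueError("n_unique must be within [1, n_samples]")
    if n_hyper + n_hypo > n_promoters:
        raise ValueError("more directed promoters than promoters")
    rng = np.random.default_rng(seed)

    promoters = [f"p1@TF{i:03d}" for i in range(1, n_promoters + 1)]
    scale = rng.lognormal(mean=2.0, sigma=0.8, size=n_promoters)
    base_cols = n_unique
    vals = rng.lognormal(mean=0.0, sigma=1.0, size=(n_promoters, base_cols)) * scale[:, None]
    vals = np.round(vals, 3)  # quantised tags, so exact duplicates stay exact

    ids = [f"sample{i:04d}" for i in range(1, base_cols)]
    ids.append(reference_column)
    order = rng.permutation(base_cols)
    columns = [ids[i] for i in order]
    matrix = pd.DataFrame(vals[:, order], index=promoters, columns=columns)

    n_dupes = n_samples - n_unique
    if n_dupes:
        src = rng.choice(columns, size=n_dupes, replace=True)
        dupes = pd.DataFrame(
            {f"dup{j:04d}_{s}": matrix[s] for j, s in enumerate(src, start=1)}
        )
        matrix = pd.concat([matrix, dupes], axis=1)
    if reference_column not in matrix.columns:
        raise ValueError(f"reference column {reference_column!r} absent")

    labels = np.array(["hyper"] * n_hyper + ["hypo"] * n_hypo
                      + ["none"] * (n_promoters - n_hyper - n_hypo))
    rng.shuffle(labels)
    directions = pd.Series(labels, index=promoters, name="direction")
    return matrix, directions
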