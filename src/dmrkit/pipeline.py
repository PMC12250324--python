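"""End-to-end pipeline wiring and the desk-scale fixture builder.

The pipeline runs the stages in dependency order — DMC/tile calling per
treatment, DMR assembly, cross-treatment sharing, regulatory annotation,
repeat-element analysis, TF-signature clustering — from a directory of input
files to a run directory of TSV tables plus a JSON manifest recording the
seed, thresholds, input checksums and per-stage counts.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation, diffmeth, dmr, io, repeats, synthetic, tfsig
from .datasets import load_caco2_tf_table

log = logging.getLogger("dmrkit")

TRACK_FILES = {
    "cgi": "cgi.bed",
    "ccre": "ccre.bed",
    "dhs": "dhs.bed",
    "ctcf": "ctcf.bed",
    "h3k4me1": "h3k4me1.bed",
    "h3k4me3": "h3k4me3.bed",
    "h3k9me3": "h3k9me3.bed",
    "h3k36me3": "h3k36me3.bed",
    "cage_tss": "cage_tss.bed",
}


@dataclass
class PipelineConfig:
    """Thresholds and paths for a pipeline run.

    Threshold defaults are the standard RRBS filter set: coverage >= 10,
    q < 0.01, |diff| >= 25, 200-bp windows, >= 4 DMCs for DMC-only regions,
    the relaxed 5-point threshold for chromosome distributions, promoters
    +-1 kb around the TSS and 2-kb island shores.
    """

    input_dir: str = "."
    out_dir: str = "run"
    seed: int = 0
    treatments: tuple[str, ...] = synthetic.TREATMENTS
    subset_chrom: str = "chr21"
    reference_column: str = "Caco-2"
    shared_pair: tuple[str, str] = ("IND10", "IND50")
    min_coverage: int = 10
    q_cut: float = 0.01
    diff_cut: float = 25.0
    window: int = 200
    min_dmcs: int = 4
    chrom_dist_diff: float = 5.0
    promoter_up: int = 1000
    promoter_down: int = 1000
    shore: int = 2000
    ccre_max_dist: int = 50_000
    n_replicates: int = 2

    def __post_init__(self) -> None:
        for name in ("min_coverage", "q_cut", "diff_cut", "window", "min_dmcs",
                     "chrom_dist_diff", "promoter_up", "promoter_down", "shore"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        self.treatments = tuple(self.treatments)
        self.shared_pair = tuple(self.shared_pair)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _expected_inputs(cfg: PipelineConfig, indir: Path) -> dict[str, Path]:
    paths = {"chrom_sizes": indir / "chrom_sizes.tsv", "genes": indir / "genes.tsv",
             "repeats": indir / "repeats.bed", "repeat_fasta": indir / "repeats.fasta",
             "tf_matrix": indir / "tf_matrix.tsv",
             "tf_directions": indir / "tf_directions.tsv"}
    for name, fn in TRACK_FILES.items():
        paths[f"track_{name}"] = indir / fn
    for cond in (synthetic.CONTROL, *cfg.treatments):
        for rep in range(1, cfg.n_replicates + 1):
            paths[f"calls_{cond}_rep{rep}"] = indir / f"{cond}_rep{rep}.tsv"
    return paths


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = _expected_inputs(cfg, indir)
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")

    manifest: dict = {
        "version": __version__,
        "libs": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "inputs": {k: _sha256(p) for k, p in sorted(inputs.items())},
        "stages": {},
        "timestamp": datetime.datetime.now().isoformat(),
    }

    chrom_sizes = dict(
        pd.read_csv(inputs["chrom_sizes"], sep="\t", header=None, names=["chrom", "size"])
        .itertuples(index=False, name=None)
    )
    genes = pd.read_csv(inputs["genes"], sep="\t")
    repeats_df = io.read_bed(inputs["repeats"], columns=io.REPEAT_BED_COLUMNS)

    def _stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        log.info("%s: %s", name, counts)

    control = [
        io.read_calltable(inputs[f"calls_{synthetic.CONTROL}_rep{r}"],
                          condition=synthetic.CONTROL)
        for r in range(1, cfg.n_replicates + 1)
    ]

    dmc_tables: dict[str, pd.DataFrame] = {}
    tile_tables: dict[str, pd.DataFrame] = {}
    dmr_tables: dict[str, pd.DataFrame] = {}
    for trt in cfg.treatments:
        treated = [
            io.read_calltable(inputs[f"calls_{trt}_rep{r}"], condition=trt)
            for r in range(1, cfg.n_replicates + 1)
        ]
        dmcs = diffmeth.call_dmcs(control, treated, cfg.min_coverage, cfg.q_cut, cfg.diff_cut)
        tiles = diffmeth.call_tiles(control, treated, cfg.window, cfg.window,
                                    cfg.min_coverage, cfg.q_cut, cfg.diff_cut)
        dmc_tables[trt], tile_tables[trt] = dmcs, tiles
        dmcs.to_csv(outdir / f"dmc_{trt}.tsv", sep="\t", index=False)
        tiles.to_csv(outdir / f"tiles_{trt}.tsv", sep="\t", index=False)
        regions, audit = dmr.assemble_dmrs(dmcs, tiles, cfg.window, cfg.min_dmcs)
        dmr_tables[trt] = regions
        audit.to_csv(outdir / f"dmr_audit_{trt}.tsv", sep="\t", index=False)
        dist = diffmeth.chromosome_distribution(dmcs, cfg.q_cut, cfg.chrom_dist_diff)
        dist.to_csv(outdir / f"chrom_distribution_{trt}.tsv", sep="\t")
        shift_stat, shift_p = diffmeth.global_shift_test(
            dmcs["m_c"] / dmcs["cov_c"], dmcs["m_t"] / dmcs["cov_t"]
        )
        flags = regions["origin_flag"].value_counts().to_dict()
        _stage(f"diffmeth_{trt}", cpgs_tested=len(dmcs),
               global_shift_p=float(shift_p),
               dmcs=int(dmcs["significant"].sum()), tiles_tested=len(tiles),
               tiles_significant=int(tiles["significant"].sum()),
               dmrs=len(regions), **{f"flag_{k}": int(v) for k, v in flags.items()})

    annotated, venn = dmr.flag_shared(dmr_tables)
    venn.to_csv(outdir / "venn.tsv", sep="\t", index=False)
    for trt, table in annotated.items():
        table.to_csv(outdir / f"dmr_{trt}.tsv", sep="\t", index=False)
        _stage(f"dmr_{trt}", total=len(table),
               hypo_pct=round(dmr.hypo_fraction(table), 2) if len(table) else float("nan"))

    # annotation of the DMRs shared by the designated treatment pair
    a, b = cfg.shared_pair
    if a in annotated and b in annotated:
        shared = annotated[a][annotated[a][f"shared_{b}"]].reset_index(drop=True)
    else:
        shared = next(iter(annotated.values()))
    promoters = annotation.make_promoters(genes, cfg.promoter_up, cfg.promoter_down,
                                          chrom_sizes)
    cgis = annotation.AnnotationTrack("cgi", io.read_bed(inputs["track_cgi"]))
    shores = annotation.make_cgi_shores(cgis, cfg.shore, chrom_sizes)
    tracks = [promoters, cgis, shores]
    for name in TRACK_FILES:
        if name == "cgi":
            continue
        tracks.append(annotation.AnnotationTrack(name, io.read_bed(inputs[f"track_{name}"])))
    matrix, summary = annotation.annotate_dmrs(shared, tracks)
    matrix.to_csv(outdir / "feature_matrix.tsv", sep="\t")
    summary.to_csv(outdir / "annotation_summary.tsv", sep="\t", index=False)
    ccre_track = next(t for t in tracks if t.name == "ccre")
    gene_list, gene_types, unassigned = annotation.assign_genes(
        shared, genes, promoters, ccre_track, cfg.ccre_max_dist
    )
    gene_list.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    gene_types.to_csv(outdir / "gene_types.tsv", sep="\t", index=False)
    for direction, rng_ in (("hypo", (-100.0, -70.0)), ("hyper", (80.0, 100.0))):
        ranked = annotation.rank_promoter_dmrs(
            annotated[a], annotated[b], promoters, direction, rng_
        ) if a in annotated and b in annotated else pd.DataFrame()
        ranked.to_csv(outdir / f"ranked_{direction}.tsv", sep="\t", index=False)
    _stage("annotation", shared_dmrs=len(shared), unique_genes=len(gene_list),
           unassigned_ccre=unassigned)

    # repeat-element analysis on significant DMCs, stratified
    strata = {}
    for trt in cfg.treatments:
        sig = dmc_tables[trt][dmc_tables[trt]["significant"]]
        strata[f"{trt} hyper"] = sig[sig["diff_meth"] > 0]
        strata[f"{trt} hypo"] = sig[sig["diff_meth"] < 0]
    _, re_summary = repeats.annotate_dmcs_repeats(strata, repeats_df, cfg.subset_chrom)
    re_summary.to_csv(outdir / "repeat_dmc_summary.tsv", sep="\t")
    repeats.repeat_proportions(repeats_df, chrom_sizes).to_csv(
        outdir / "repeat_proportions_genome.tsv", sep="\t", index=False)
    repeats.repeat_proportions(repeats_df, chrom_sizes, cfg.subset_chrom).to_csv(
        outdir / "repeat_proportions_subset.tsv", sep="\t", index=False)
    fams = io.read_repeat_fasta(inputs["repeat_fasta"])
    repeats.cpg_content(fams).to_csv(outdir / "repeat_cpg_content.tsv", sep="\t", index=False)
    for scope, chrom in (("genome", None), ("subset", cfg.subset_chrom)):
        dist, other = repeats.re_distribution(strata, repeats_df, chrom)
        dist.to_csv(outdir / f"re_distribution_{scope}.tsv", sep="\t")
        other.to_csv(outdir / f"re_distribution_{scope}_other.tsv", sep="\t")
    _stage("repeats", families=len(fams),
           repeat_dmcs=int(re_summary.loc["All DMC in RE"].sum()))

    # TF signature simulation and clustering
    tf_matrix = io.read_matrix(inputs["tf_matrix"])
    directions = io.read_directions(inputs["tf_directions"])
    profiles = tfsig.simulate_profiles(tf_matrix, directions, cfg.reference_column)
    augmented = pd.concat(
        [tf_matrix, profiles.rename(columns=lambda c: f"synthetic_{c}")], axis=1
    )
    zmat = tfsig.zscore_rows(augmented)
    reduced, dropped = tfsig.dedup_samples(zmat)
    syn_cols = [f"synthetic_{c}" for c in tfsig.EFFECT_LEVELS]
    linkage_matrix, report = tfsig.cluster_samples(reduced, syn_cols)
    pd.DataFrame(linkage_matrix, columns=["left", "right", "height", "size"]).to_csv(
        outdir / "tf_linkage.tsv", sep="\t", index=False)
    report.to_csv(outdir / "tf_neighbors.tsv", sep="\t", index=False)
    dropped.to_csv(outdir / "tf_duplicates.tsv", sep="\t", index=False)
    _stage("tfsig", samples=tf_matrix.shape[1],
           unique_samples=reduced.shape[1] - len(syn_cols),
           duplicates_dropped=len(dropped))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir


def _random_repeat_sequences(
    families: Mapping[str, tuple[str, int, int]], rng: np.random.Generator,
    n_per_family: int = 8,
) -> dict[str, list[str]]:
    """Random sequences per family with family-specific CpG enrichment."""
    cg_boost = {"Alu": 3.0, "MIR": 2.0, "L1": 1.2, "L2": 1.2, "rRNA": 2.5}
    out: dict[str, list[str]] = {}
    bases = np.array(list("ACGT"))
    for fam, (_cls, _copies, length) in families.items():
        seqs = []
        boost = cg_boost.get(fam, 1.0)
        for _ in range(n_per_family):
            seq = bases[rng.integers(0, 4, size=length)]
            # plant extra CG dinucleotides proportional to the boost
            n_cg = int(length / 16 * boost)
            pos = rng.choice(length - 1, size=n_cg, replace=False)
            seq[pos] = "C"
            seq[pos + 1] = "G"
            seqs.append("".join(seq))
        out[fam] = seqs
    return out


def build_fixtures(out_dir: str | Path, seed: int = 0,
                   config: synthetic.LayoutConfig | None = None,
                   n_effect_regions: int = 60) -> Path:
    """Generate the desk-scale input dataset for an end-to-end run.

    Writes call tables for control plus three treatments (2 replicates
    each), all annotation tracks, repeat sequences, the expression matrix
    with its direction map, the planted-effect truth table, and a copy of
    the bundled Caco-2 TF promoter table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout_cfg = config or synthetic.LayoutConfig(
        chromosomes=(("chr1", 400_000), ("chr21", 400_000)),
        n_cgis=25,
        spacing={"CGI": 10.0, "promoter": 20.0, "repeat": 40.0, "background": 60.0},
    )
    layout = synthetic.generate_layout(layout_cfg, seed=seed)
    n_bg = max(1, n_effect_regions - n_effect_regions // 3)
    n_rep = max(1, n_effect_regions // 6)
    n_cgi = max(1, n_effect_regions - n_bg - n_rep)
    effects = synthetic.plant_effects(
        layout, n_bg, (40.0, -40.0), seed=seed + 1
    )
    # hypomethylation of high-baseline repeats, shared by two doses only,
    # and CGI hypermethylation private to one dose: exercises the Venn and
    # repeat-element stages
    effects += synthetic.plant_effects(
        layout, n_rep, -40.0, treatments=("IND10", "IND50"),
        compartment="repeat", min_cpgs=4, seed=seed + 5,
    )
    effects += synthetic.plant_effects(
        layout, n_cgi, 40.0, treatments=("IND50",),
        compartment="CGI", min_cpgs=8, seed=seed + 6,
    )
    callsets, truth = synthetic.generate_methylome(layout, effects, seed=seed + 2)

    pd.DataFrame(layout.chromosomes).to_csv(
        out / "chrom_sizes.tsv", sep="\t", header=False, index=False)
    layout.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    for name, fn in TRACK_FILES.items():
        io.write_bed(layout.tracks[name], out / fn)
    io.write_bed(layout.tracks["repeats"], out / "repeats.bed")
    io.write_bed(truth, out / "truth.bed")
    for cond, sets in callsets.items():
        for i, cs in enumerate(sets, start=1):
            io.write_calltable(cs, out / f"{cond}_rep{i}.tsv")

    rng = np.random.default_rng(seed + 3)
    fams = _random_repeat_sequences(dict(layout_cfg.repeat_families), rng)
    io.write_repeat_fasta(fams, out / "repeats.fasta")

    matrix, directions = synthetic.generate_tf_matrix(
        n_promoters=23, n_samples=120, n_unique=100, seed=seed + 4
    )
    io.write_matrix(matrix, out / "tf_matrix.tsv")
    io.write_directions(directions, out / "tf_directions.tsv")
    load_caco2_tf_table().to_csv(out / "caco2_tf_promoters.tsv", sep="\t", index=False)
    return out
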