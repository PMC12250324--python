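"""Promoter/shore construction, interval overlap engine, gene assignment."""

import numpy as np
import pandas as pd
import pytest

import dmrkit as dk
from dmrkit.annotation import AnnotationTrack, merge_intervals

from conftest import allpairs_overlap


def gene_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "tss", "strand", "symbol", "gene_type"])


class TestPromoters:
    def test_plus_strand_window(self):
        track = dk.make_promoters(gene_table([("chr1", 5000, "+", "G1", "protein_coding")]))
        row = track.intervals.iloc[0]
        assert (row["start"], row["end"]) == (4000, 6000)

    def test_minus_strand_mirrors_roles(self):
        sym = dk.make_promoters(gene_table([("chr1", 5000, "-", "G1", "protein_coding")]))
        row = sym.intervals.iloc[0]
        assert (row["start"], row["end"]) == (4000, 6000)
        asym = dk.make_promoters(
            gene_table([("chr1", 5000, "-", "G1", "protein_coding")]), up=1500, down=500
        )
        row = asym.intervals.iloc[0]
        # upstream of a minus-strand gene extends to the right
        assert (row["start"], row["end"]) == (4500, 6500)

    def test_clipping_and_rejection(self):
        genes = gene_table([
            ("chr1", 300, "+", "NearEdge", "protein_coding"),
            ("chr1", 99_999, "+", "Outside", "protein_coding"),
        ])
        with pytest.warns(UserWarning, match="outside"):
            track = dk.make_promoters(genes, chrom_sizes={"chr1": 50_000})
        assert len(track.intervals) == 1
        assert track.intervals.iloc[0]["start"] == 0

    def test_shuffling_input_does_not_change_output(self):
        rng = np.random.default_rng(3)
        rows = [("chr1", int(p), "+", f"G{i}", "protein_coding")
                for i, p in enumerate(rng.integers(2000, 90_000, 20))]
        a = dk.make_promoters(gene_table(rows)).intervals
        b = dk.make_promoters(gene_table([rows[i] for i in rng.permutation(20)])).intervals
        pd.testing.assert_frame_equal(
            a.sort_values(["start", "label"]).reset_index(drop=True),
            b.sort_values(["start", "label"]).reset_index(drop=True),
        )


class TestShores:
    def test_isolated_island_has_symmetric_shores(self):
        cgis = pd.DataFrame([("chr1", 10_000, 11_000)], columns=["chrom", "start", "end"])
        shores = dk.make_cgi_shores(cgis).intervals
        assert [tuple(r) for r in shores[["start", "end"]].to_numpy()] == [
            (8000, 10_000), (11_000, 13_000)
        ]

    def test_close_islands_truncate_the_gap_shore(self):
        cgis = pd.DataFrame(
            [("chr1", 10_000, 11_000), ("chr1", 12_000, 13_000)],
            columns=["chrom", "start", "end"],
        )
        shores = dk.make_cgi_shores(cgis).intervals
        spans = sorted(tuple(r) for r in shores[["start", "end"]].to_numpy())
        # the 1-kb gap yields two abutting shores, neither entering an island
        assert spans == [(8000, 10_000), (11_000, 12_000), (11_000, 12_000),
                         (13_000, 15_000)] or spans == [
            (8000, 10_000), (11_000, 12_000), (13_000, 15_000)]
        for s, e in spans:
            assert not (s < 11_000 and e > 10_000) or (s >= 11_000 or e <= 10_000)

    def test_chromosome_bound_clipping(self):
        cgis = pd.DataFrame([("chr1", 500, 1500)], columns=["chrom", "start", "end"])
        shores = dk.make_cgi_shores(cgis, chrom_sizes={"chr1": 2000}).intervals
        spans = sorted(tuple(r) for r in shores[["start", "end"]].to_numpy())
        assert spans == [(0, 500), (1500, 2000)]


class TestOverlapEngine:
    def test_matches_allpairs_checker(self):
        rng = np.random.default_rng(11)
        track_df = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 150),
            "start": (s := rng.integers(0, 50_000, 150)),
            "end": s + rng.integers(50, 800, 150),
        })
        dmrs = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 80),
            "start": (q := rng.integers(0, 50_000, 80) // 200 * 200),
            "end": q // 200 * 200 + 200,
            "direction": rng.choice(["hyper", "hypo"], 80),
        })
        track = AnnotationTrack("t", track_df)
        matrix, summary = dk.annotate_dmrs(dmrs, [track])
        assert list(matrix["t"]) == allpairs_overlap(dmrs, track_df)
        assert summary.loc[0, "tot"] == sum(matrix["t"])
        assert summary.loc[0, "hyper"] + summary.loc[0, "hypo"] == summary.loc[0, "tot"]

    def test_halfopen_abutment_is_not_overlap(self):
        track = AnnotationTrack("t", pd.DataFrame(
            [("chr1", 1000, 1200)], columns=["chrom", "start", "end"]))
        dmrs = pd.DataFrame(
            [("chr1", 800, 1000, "hyper"), ("chr1", 999, 1001, "hyper")],
            columns=["chrom", "start", "end", "direction"],
        )
        matrix, _ = dk.annotate_dmrs(dmrs, [track])
        assert list(matrix["t"]) == [False, True]

    def test_multi_membership_counts_in_every_track(self):
        prom = AnnotationTrack("prom", pd.DataFrame(
            [("chr1", 0, 2000)], columns=["chrom", "start", "end"]))
        cgi = AnnotationTrack("cgi", pd.DataFrame(
            [("chr1", 100, 600)], columns=["chrom", "start", "end"]))
        dmrs = pd.DataFrame([("chr1", 200, 400, "hyper")],
                            columns=["chrom", "start", "end", "direction"])
        _, summary = dk.annotate_dmrs(dmrs, [prom, cgi])
        assert (summary["tot"] == 1).all()

    def test_empty_track_warns_and_zeroes(self):
        empty = AnnotationTrack("none", pd.DataFrame(columns=["chrom", "start", "end"]))
        dmrs = pd.DataFrame([("chr1", 0, 200, "hyper")],
                            columns=["chrom", "start", "end", "direction"])
        with pytest.warns(UserWarning, match="no intervals"):
            _, summary = dk.annotate_dmrs(dmrs, [empty])
        assert summary.loc[0, "tot"] == 0


class TestGeneAssignment:
    def test_two_dmrs_in_one_promoter_count_the_gene_once(self):
        genes = gene_table([("chr1", 5000, "+", "G1", "protein_coding")])
        dmrs = pd.DataFrame(
            [("chr1", 4200, 4400, "hyper"), ("chr1", 5200, 5400, "hyper")],
            columns=["chrom", "start", "end", "direction"],
        )
        out, props, _ = dk.assign_genes(dmrs, genes)
        assert list(out["symbol"]) == ["G1"]
        assert props.loc[0, "pct"] == 100.0

    def test_gene_type_proportions(self):
        rows = ([("chr1", 10_000 * (i + 1), "+", f"C{i}", "protein_coding") for i in range(6)]
                + [("chr1", 10_000 * (i + 7), "+", f"L{i}", "lncRNA") for i in range(3)]
                + [("chr1", 100_000, "+", "M0", "miRNA")])
        genes = gene_table(rows)
        dmrs = pd.DataFrame(
            [("chr1", g[1] - 100, g[1] + 100, "hyper") for g in rows],
            columns=["chrom", "start", "end", "direction"],
        )
        _, props, _ = dk.assign_genes(dmrs, genes)
        got = dict(zip(props["gene_type"], props["pct"]))
        assert got == {"protein_coding": 60.0, "lncRNA": 30.0, "miRNA": 10.0}

    def test_nearest_tss_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        genes = gene_table([
            ("chr1", int(p), "+", f"G{i}", "protein_coding")
            for i, p in enumerate(sorted(rng.integers(5000, 400_000, 25)))
        ])
        ccre_df = pd.DataFrame(
            [("chr1", int(s), int(s) + 300) for s in rng.integers(0, 400_000, 15)],
            columns=["chrom", "start", "end"],
        )
        ccres = AnnotationTrack("ccre", ccre_df)
        dmrs = pd.DataFrame(
            [("chr1", int(s), int(s) + 200, "hyper")
             for s in ccre_df["start"] + 50],
            columns=["chrom", "start", "end", "direction"],
        )
        promoters = dk.make_promoters(genes)
        out, _, unassigned = dk.assign_genes(dmrs, genes, promoters, ccres, max_dist=50_000)
        # brute-force: for each DMR not touching a promoter, nearest TSS by midpoint
        prom_df = promoters.intervals
        expect = set()
        n_unassigned = 0
        for _, d in dmrs.iterrows():
            in_prom = [p for _, p in prom_df.iterrows()
                       if d["start"] < p["end"] and p["start"] < d["end"]]
            if in_prom:
                expect.update(p["label"] for p in in_prom)
                continue
            mid = (d["start"] + d["end"]) // 2
            dists = [(abs(g["tss"] - mid), g["symbol"]) for _, g in genes.iterrows()]
            dmin, sym = min(dists)
            if dmin <= 50_000:
                expect.add(sym)
            else:
                n_unassigned += 1
        assert set(out["symbol"]) == expect
        assert unassigned == n_unassigned


class TestRanking:
    def _dmrs(self, entries):
        return pd.DataFrame(
            [dict(chrom="chr1", start=s, end=s + 200,
                  direction="hypo" if d < 0 else "hyper", diff_meth=d,
                  n_dmc=5, origin_flag="T") for s, d in entries]
        )

    def test_closed_interval_boundaries(self):
        genes = gene_table([
            ("chr1", 1000, "+", "A", "protein_coding"),
            ("chr1", 5000, "+", "B", "protein_coding"),
            ("chr1", 9000, "+", "C", "protein_coding"),
        ])
        promoters = dk.make_promoters(genes)
        dmrs = self._dmrs([(800, -100.0), (4800, -70.0), (8800, -65.0)])
        ranked = dk.rank_promoter_dmrs(dmrs, dmrs, promoters, "hypo", (-100.0, -70.0))
        # -100 and -70 included (closed interval), -65 excluded
        assert list(ranked["gene"]) == ["A", "B"]

    def test_ranked_output_matches_sort_oracle(self):
        entries = [(1000 + 10_000 * i, d) for i, d in
                   enumerate([-88.6, -96.0, -70.8, -81.0, -80.0, -80.0])]
        genes = gene_table([
            ("chr1", s + 100, "+", sym, "protein_coding")
            for (s, _), sym in zip(entries, ["SHH", "ONECUT1", "ACY3", "DIO3", "DSCAM", "AAAA"])
        ])
        promoters = dk.make_promoters(genes)
        dmrs = self._dmrs(entries)
        ranked = dk.rank_promoter_dmrs(dmrs, dmrs, promoters, "hypo", (-100.0, -70.0))
        oracle = sorted(
            zip(["SHH", "ONECUT1", "ACY3", "DIO3", "DSCAM", "AAAA"],
                [-88.6, -96.0, -70.8, -81.0, -80.0, -80.0]),
            key=lambda t: (-abs(t[1]), t[0]),
        )
        assert list(ranked["gene"]) == [g for g, _ in oracle]
        # alphabetical tie-break between the two genes at -80
        ia, id_ = list(ranked["gene"]).index("AAAA"), list(ranked["gene"]).index("DSCAM")
        assert ia < id_

    def test_unshared_dmrs_are_excluded(self):
        genes = gene_table([("chr1", 1000, "+", "A", "protein_coding")])
        promoters = dk.make_promoters(genes)
        a = self._dmrs([(800, -90.0)])
        b = self._dmrs([(3000, -90.0)])
        ranked = dk.rank_promoter_dmrs(a, b, promoters, "hypo", (-100.0, -70.0))
        assert ranked.empty


def test_merge_intervals_unions_overlaps():
    df = pd.DataFrame(
        [("chr1", 0, 100), ("chr1", 50, 150), ("chr1", 200, 300)],
        columns=["chrom", "start", "end"],
    )
    merged = merge_intervals(df)
    assert [tuple(r) for r in merged[["start", "end"]].to_numpy()] == [(0, 150), (200, 300)]
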