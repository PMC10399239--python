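"""Window tiling, Fisher exact test, DMR/DMG calling and metaprofiles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import linregress

from methwin import io as mio
from methwin import stats, windows
from methwin.windows import (
    aggregate_window_counts,
    call_dmrs,
    dmg_fraction,
    fisher_exact_many,
    fisher_exact_two_tailed,
    metaprofile,
    summarize_dmgs,
    tile_windows,
)

from _oracles import fisher_oracle, fisher_oracle_margins


class TestTileWindows:
    def test_default_geometry(self):
        tiles = tile_windows(3000, 50)
        assert len(tiles) == 60
        assert tiles["start"].iloc[0] == 0 and tiles["end"].iloc[-1] == 3000

    def test_two_window_toy(self):
        tiles = tile_windows(100, 50)
        assert list(map(tuple, tiles[["start", "end"]].to_numpy())) == [(0, 50), (50, 100)]

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            tile_windows(3000, 49)

    def test_union_and_disjointness_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = int(rng.integers(1, 100))
            L = w * int(rng.integers(1, 80))
            tiles = tile_windows(L, w)
            assert (tiles["end"] - tiles["start"]).eq(w).all()
            assert (tiles["start"].iloc[1:].to_numpy() == tiles["end"].iloc[:-1].to_numpy()).all()
            assert tiles["start"].iloc[0] == 0 and tiles["end"].iloc[-1] == L


class TestFisherExact:
    def test_identical_rows_give_one(self):
        assert fisher_exact_two_tailed(5, 5, 5, 5) == 1.0

    def test_extreme_table_closed_form(self):
        # [[0,50],[50,0]]: only the two extreme tables are as unlikely,
        # p = 2 / C(100, 50)
        p = fisher_exact_two_tailed(0, 50, 50, 0)
        assert p == pytest.approx(2 / math.comb(100, 50), rel=1e-9)
        assert p < 1e-20

    def test_zero_margin_means_no_information(self):
        assert fisher_exact_two_tailed(0, 0, 3, 7) == 1.0
        assert fisher_exact_two_tailed(0, 5, 0, 7) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact_two_tailed(-1, 5, 5, 5)

    def test_matches_bruteforce_on_moderate_tables(self):
        rng = np.random.default_rng(1)
        tables = rng.integers(0, 30, size=(300, 4))
        p_impl = fisher_exact_many(*tables.T)
        for (a, b, c, d), p in zip(tables, p_impl):
            p_oracle = fisher_oracle(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(2)
        tables = rng.integers(0, 80, size=(200, 4))
        p_impl = fisher_exact_many(*tables.T)
        for (a, b, c, d), p in zip(tables, p_impl):
            assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], rel=1e-6)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        tables = rng.integers(0, 60, size=(100, 4))
        p1 = fisher_exact_many(tables[:, 0], tables[:, 1], tables[:, 2], tables[:, 3])
        p2 = fisher_exact_many(tables[:, 2], tables[:, 3], tables[:, 0], tables[:, 1])
        np.testing.assert_allclose(p1, p2, rtol=1e-12)


def window_frame(rows, context="CpG"):
    """rows: (gene_id, window_index, meth, unmeth)."""
    df = pd.DataFrame(rows, columns=["gene_id", "window_index", "meth", "unmeth"])
    df["context"] = context
    cov = df["meth"] + df["unmeth"]
    df["mean_pct"] = np.where(cov > 0, 100.0 * df["meth"] / cov, np.nan)
    return df


class TestCallDmrs:
    def test_identical_groups_not_called(self):
        a = window_frame([("g1", 0, 10, 90)])
        out = call_dmrs(a, a.copy())
        r = out.iloc[0]
        assert r["p_value"] == 1.0 and r["delta_pct"] == 0.0 and not r["is_dmr"]

    def test_large_shift_called(self):
        a = window_frame([("g1", 0, 5, 95)])
        b = window_frame([("g1", 0, 40, 60)])
        out = call_dmrs(a, b)
        r = out.iloc[0]
        assert r["delta_pct"] == pytest.approx(35.0)
        assert r["p_value"] == pytest.approx(fisher_oracle(5, 95, 40, 60), rel=1e-9)
        assert r["p_value"] < 0.05 and r["is_dmr"]

    def test_exact_20_point_delta_is_not_a_dmr(self):
        # effect rule is strictly "> 20 points"
        a = window_frame([("g1", 0, 5, 95)])
        b = window_frame([("g1", 0, 25, 75)])
        out = call_dmrs(a, b)
        r = out.iloc[0]
        assert r["delta_pct"] == pytest.approx(20.0)
        assert r["p_value"] < 0.05
        assert not r["is_dmr"]

    def test_sign_flips_and_p_constant_under_swap(self):
        a = window_frame([("g1", 0, 5, 95), ("g1", 1, 30, 70)])
        b = window_frame([("g1", 0, 40, 60), ("g1", 1, 10, 90)])
        ab = call_dmrs(a, b)
        ba = call_dmrs(b, a)
        np.testing.assert_allclose(ab["delta_pct"], -ba["delta_pct"])
        np.testing.assert_allclose(ab["p_value"], ba["p_value"])

    def test_zero_coverage_window_is_no_call(self):
        a = window_frame([("g1", 0, 0, 0)])
        b = window_frame([("g1", 0, 10, 10)])
        out = call_dmrs(a, b)
        r = out.iloc[0]
        assert not r["tested"] and not r["is_dmr"] and math.isnan(r["p_value"])

    def test_mismatched_grids_rejected(self):
        a = window_frame([("g1", 0, 1, 1)])
        b = window_frame([("g1", 1, 1, 1)])
        with pytest.raises(ValueError, match="window grid"):
            call_dmrs(a, b)


class TestAggregateWindows:
    def test_single_site_lands_in_its_window(self, ):
        ann = pd.DataFrame(
            {
                "condition": ["cool"],
                "part": ["apical"],
                "gene_id": ["g1"],
                "position": [170],
                "strand": ["+"],
                "context": ["CpG"],
                "region": ["promoter"],
                "meth": [5],
                "unmeth": [15],
            }
        )
        out = aggregate_window_counts(ann, {"g1": 200}, window_size=50)
        w3 = out[out["window_index"] == 3].iloc[0]
        assert (w3["meth"], w3["unmeth"]) == (5, 15)
        assert w3["mean_pct"] == pytest.approx(25.0)
        empty = out[out["window_index"] == 0].iloc[0]
        assert empty["meth"] == 0 and math.isnan(empty["mean_pct"])

    def test_window_sums_conserve_gene_totals(self, default_annotated, default_bundle):
        lengths = {g: r.length for g, r in default_bundle.regions.items()}
        out = aggregate_window_counts(default_annotated, lengths, 50)
        window_totals = out.groupby("gene_id")[["meth", "unmeth"]].sum()
        gene_totals = default_annotated.groupby("gene_id")[["meth", "unmeth"]].sum()
        pd.testing.assert_frame_equal(
            window_totals, gene_totals, check_like=True, check_dtype=False
        )

    def test_grid_is_complete(self, default_annotated, default_bundle):
        lengths = {g: r.length for g, r in default_bundle.regions.items()}
        out = aggregate_window_counts(default_annotated, lengths, 50)
        per_group = out.groupby(["condition", "part"]).size()
        assert (per_group == len(lengths) * 60).all()


class TestDmgSummary:
    def test_single_context_dmr_flags_gene(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "window_index": [0, 1, 0],
                "context": ["CpG", "CHH", "CpG"],
                "is_dmr": [True, False, False],
            }
        )
        out = summarize_dmgs(calls).set_index("gene_id")
        assert bool(out.loc["g1", "is_dmg_CpG"]) and bool(out.loc["g1", "is_dmg_any"])
        assert not out.loc["g2", "is_dmg_any"]
        assert dmg_fraction(out.reset_index()) == pytest.approx(0.5)

    def test_no_dmrs_no_dmgs(self):
        calls = pd.DataFrame(
            {"gene_id": ["g1"], "window_index": [0], "context": ["CpG"], "is_dmr": [False]}
        )
        out = summarize_dmgs(calls)
        assert not out["is_dmg_any"].any()


class TestMetaprofile:
    def make_annotated(self, gene_specs, window_size=50, length=100):
        rows = []
        for gene, win_means in gene_specs:
            for w, pct in enumerate(win_means):
                if pct is None:
                    continue
                rows.append(
                    {
                        "condition": "cool",
                        "part": "apical",
                        "replicate": 1,
                        "gene_id": gene,
                        "position": w * window_size + 10,
                        "strand": "+",
                        "context": "CpG",
                        "region": "promoter",
                        "meth": int(pct),
                        "unmeth": 100 - int(pct),
                    }
                )
        lengths = {g: length for g, _ in gene_specs}
        return pd.DataFrame(rows), lengths

    def test_single_gene_curve_is_its_window_means(self):
        ann, lengths = self.make_annotated([("g1", [10, 30])])
        curve = metaprofile(ann, lengths, 50)
        assert list(curve["mean_pct"]) == pytest.approx([10.0, 30.0])

    def test_mean_across_genes(self):
        ann, lengths = self.make_annotated([("g1", [10, 20]), ("g2", [30, 40])])
        curve = metaprofile(ann, lengths, 50)
        assert list(curve["mean_pct"]) == pytest.approx([20.0, 30.0])

    def test_uncovered_windows_excluded_not_zero(self):
        ann, lengths = self.make_annotated([("g1", [10, None]), ("g2", [30, 40])])
        curve = metaprofile(ann, lengths, 50).set_index("window_index")
        assert curve.loc[1, "mean_pct"] == pytest.approx(40.0)

    def test_recovers_generating_promoter_slope(self, default_bundle, default_annotated):
        cfg = default_bundle.config
        lengths = {g: r.length for g, r in default_bundle.regions.items()}
        cool = default_annotated[
            (default_annotated["condition"] == "cool")
            & (default_annotated["part"] == "apical")
        ]
        curve = metaprofile(cool, lengths, cfg.window_size, context="CpG")
        curve = curve[(curve["condition"] == "cool") & (curve["part"] == "apical")]
        n_prom = cfg.tss_offset // cfg.window_size
        prom = curve[curve["window_index"] < n_prom]
        centers = prom["window_index"] * cfg.window_size + cfg.window_size / 2
        fit = linregress(centers, prom["mean_pct"])
        # constitutively unmethylated sites and epimutation flips dilute the
        # expected curve uniformly by the active-site probability
        f = cfg.unmethylated_site_fraction["CpG"]
        eps = cfg.epimutation_rate
        active = (1.0 - f) * (1.0 - eps) + f * eps
        expected_slope = (
            100.0
            * cfg.base_level["CpG"]
            * active
            * (cfg.promoter_end_multiplier - cfg.promoter_start_multiplier)
            / (cfg.tss_offset - 1)
        )
        assert fit.slope < 0
        assert fit.slope == pytest.approx(expected_slope, rel=0.15)
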