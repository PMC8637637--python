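"""Leave-out robustness, weighting, binarization and alternate extractions."""

import numpy as np
import pandas as pd
import pytest

import wealthbridge as wb
from wealthbridge.datatypes import Asset, AssetDictionary


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

class TestBinarize:
    @pytest.fixture()
    def mixed_panel(self):
        df = pd.DataFrame({
            "household_id": [1, 2, 3, 4],
            "wave_id": 1, "year": 2000, "participation": True,
            "tv": [0, 1, 1, 0],
            "roof": ["Low", "Medium", "High", "High"],
            "crowding": [0.5, 0.75, 0.80, 1.4],
            "goats": [0, 1, 3, 7],
        })
        d = AssetDictionary([
            Asset("tv", "binary", (1,), (0, 1), "positive"),
            Asset("roof", "ordinal", (1,), ("Low", "Medium", "High"),
                  "positive"),
            Asset("crowding", "continuous", (1,), None, "positive"),
            Asset("goats", "count", (1,), None, "negative"),
        ])
        panel = wb.PanelDataset(
            data=df, asset_columns=["tv", "roof", "crowding", "goats"])
        return panel, d

    def test_ordinal_top_category_versus_rest(self, mixed_panel):
        out, _ = wb.binarize_for_alternates(*mixed_panel)
        assert out.data["roof"].tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_crowding_cut_is_strict(self, mixed_panel):
        out, _ = wb.binarize_for_alternates(*mixed_panel)
        # > 0.75 rooms per member codes 1; 0.75 itself codes 0
        assert out.data["crowding"].tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_binary_passes_through(self, mixed_panel):
        out, d_bin = wb.binarize_for_alternates(*mixed_panel)
        assert out.data["tv"].tolist() == [0.0, 1.0, 1.0, 0.0]
        assert all(d_bin[a].measurement_type == "binary" for a in d_bin.names)

    def test_count_split_at_pooled_median(self, mixed_panel):
        out, _ = wb.binarize_for_alternates(*mixed_panel)
        assert out.data["goats"].tolist() == [0.0, 0.0, 1.0, 1.0]


# ---------------------------------------------------------------------------
# inverse-wave-size weighting
# ---------------------------------------------------------------------------

class TestWeightedVariant:
    def test_equal_wave_sizes_reproduce_benchmark_exactly(self):
        cfg = wb.SyntheticConfig(n_households=400, seed=41,
                                 dropout_probability=0.0)
        panel, _ = wb.generate_panel(cfg)
        d = cfg.asset_dictionary()
        common = wb.select_common_assets(d, panel.waves)
        model = wb.fit_harmonized_index(panel, d, assets=common)
        scores = wb.score(model, panel)
        wmodel, rho = wb.weighted_variant(panel, d, scores, assets=common)
        assert rho == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(wmodel.loadings, model.loadings, atol=1e-8)

    def test_single_wave_weighted_is_identity(self):
        cfg = wb.SyntheticConfig(
            n_households=400, n_waves=1, wave_years=(1990,),
            secular_trend=(0.0,), dropout_probability=0.0, seed=43)
        panel, _ = wb.generate_panel(cfg)
        d = cfg.asset_dictionary()
        common = wb.select_common_assets(d, panel.waves)
        model = wb.fit_harmonized_index(panel, d, assets=common)
        scores = wb.score(model, panel)
        _, rho = wb.weighted_variant(panel, d, scores, assets=common)
        assert rho == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# leave-out experiments
# ---------------------------------------------------------------------------

class TestDropRobustness:
    def test_dropping_uninformative_asset_changes_nothing(self, bundle500):
        cfg = wb.SyntheticConfig(
            n_households=500, seed=11, n_binary_assets=11,
            loading_vector=(0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.7, 0.6,
                            -0.5, -0.55, 0.0, 0.7))
        full, truth = wb.generate_panel(cfg)
        panel = wb.apply_missingness(full, cfg, truth)
        d = cfg.asset_dictionary()
        common = wb.select_common_assets(d, panel.waves)
        imputed = wb.impute_missing(panel, common, d)
        model = wb.fit_harmonized_index(imputed, d, assets=common)
        scores = wb.score(model, imputed)
        table = wb.drop_robustness(imputed, d, scores, mode="asset",
                                   assets=common)
        null_row = table[table["dropped_asset"] == "asset_11"]
        assert float(null_row["rho"].iloc[0]) >= 0.99

    def test_dropping_duplicated_asset_changes_nothing(self):
        rng = np.random.default_rng(47)
        n = 2000
        w = rng.normal(size=n)
        cols = {f"a{j}": (0.7 * w + 0.71 * rng.normal(size=n)
                          > 0.15 * (j - 5)).astype(int) for j in range(10)}
        cols["dup"] = cols["a0"].copy()
        df = pd.DataFrame(cols)
        df.insert(0, "household_id", np.arange(n))
        df.insert(1, "wave_id", 1)
        df.insert(2, "year", 2000)
        df.insert(3, "participation", True)
        panel = wb.PanelDataset(data=df, asset_columns=list(cols))
        d = AssetDictionary([
            Asset(c, "binary", (1,), (0, 1), "positive") for c in cols])
        model = wb.fit_harmonized_index(panel, d)
        scores = wb.score(model, panel)
        table = wb.drop_robustness(panel, d, scores, mode="asset")
        dup_row = table[table["dropped_asset"] == "dup"]
        assert float(dup_row["rho"].iloc[0]) >= 0.99

    def test_under_determined_drops_skipped(self):
        rng = np.random.default_rng(48)
        n = 300
        w = rng.normal(size=n * 3)
        df = pd.DataFrame({
            "household_id": np.tile(np.arange(n), 3),
            "wave_id": np.repeat([1, 2, 3], n),
            "year": np.repeat([2000, 2005, 2010], n),
            "participation": True,
            "a0": (w + rng.normal(size=3 * n) > 0).astype(int),
            "a1": (w + rng.normal(size=3 * n) > 0.3).astype(int),
        })
        panel = wb.PanelDataset(data=df, asset_columns=["a0", "a1"])
        d = AssetDictionary([
            Asset(c, "binary", (1, 2, 3), (0, 1), "positive")
            for c in ("a0", "a1")])
        model = wb.fit_harmonized_index(panel, d)
        scores = wb.score(model, panel)
        table = wb.drop_robustness(panel, d, scores, mode="asset")
        assert len(table) == 0  # any drop would leave a single asset


# ---------------------------------------------------------------------------
# alternate extraction procedures
# ---------------------------------------------------------------------------

def _one_wave_binary_panel(n=2000, seed=51, lams=(0.8, 0.7, 0.6, 0.75, -0.5)):
    rng = np.random.default_rng(seed)
    w = rng.normal(size=n)
    cols = {}
    for j, lam in enumerate(lams):
        u = rng.normal(size=n)
        cols[f"a{j}"] = (lam * w + np.sqrt(1 - lam ** 2) * u > 0).astype(int)
    df = pd.DataFrame(cols)
    df.insert(0, "household_id", np.arange(n))
    df.insert(1, "wave_id", 1)
    df.insert(2, "year", 2000)
    df.insert(3, "participation", True)
    panel = wb.PanelDataset(data=df, asset_columns=list(cols))
    d = AssetDictionary([
        Asset(f"a{j}", "binary", (1,), (0, 1),
              "positive" if lam > 0 else "negative")
        for j, lam in enumerate(lams)])
    return panel, d, w


class TestAlternates:
    def test_two_variable_pearson_pca_is_symmetric(self):
        panel, d, _ = _one_wave_binary_panel(lams=(0.7, 0.7), seed=53)
        model = wb.fit_harmonized_index(panel, d)
        scores = wb.score(model, panel)
        alt, _ = wb.alternate_extraction(panel, d, scores, "pca_pearson")
        assert alt.loadings[0] == pytest.approx(alt.loadings[1], abs=1e-10)
        # closed form: first PC of a 2x2 correlation matrix weights the
        # standardized indicators equally, so score is proportional to z1+z2
        codes = panel.encoded(d)
        z = ((codes - codes.mean()) / codes.std(ddof=0)).to_numpy()
        expected = z.sum(axis=1)
        expected = (expected - expected.mean()) / expected.std()
        alt_scores = wb.score(alt, panel).table["score"].to_numpy()
        assert np.allclose(np.abs(alt_scores), np.abs(expected), atol=1e-10)

    @pytest.mark.parametrize("method", wb.sensitivity.ALTERNATE_METHODS)
    def test_each_method_tracks_benchmark_on_one_factor_panel(self, method):
        panel, d, _ = _one_wave_binary_panel(n=2000, seed=55)
        model = wb.fit_harmonized_index(panel, d)
        scores = wb.score(model, panel)
        _, rho = wb.alternate_extraction(panel, d, scores, method)
        assert rho >= 0.9

    def test_efa_recovers_one_factor_loadings(self):
        lams = (0.8, 0.7, 0.6, 0.75, -0.5, 0.65)
        panel, d, _ = _one_wave_binary_panel(n=10000, seed=57, lams=lams)
        corr = wb.mixed_corr_matrix(panel, d)
        load, heywood = wb.principal_axis_factoring(corr.rho)
        if load[0] < 0:
            load = -load
        assert not heywood
        assert np.all(np.sign(load) == np.sign(lams))
        assert np.allclose(load, lams, atol=0.05)

    def test_relabeling_households_leaves_scores_invariant(self):
        panel, d, _ = _one_wave_binary_panel(n=500, seed=59)
        model = wb.fit_harmonized_index(panel, d)
        scores = wb.score(model, panel)
        relabeled = panel.copy()
        relabeled.data["household_id"] = relabeled.data["household_id"] + 10_000
        for method in wb.sensitivity.ALTERNATE_METHODS:
            _, rho_a = wb.alternate_extraction(panel, d, scores, method)
            re_scores = wb.score(model, relabeled)
            _, rho_b = wb.alternate_extraction(relabeled, d, re_scores, method)
            assert rho_a == pytest.approx(rho_b, abs=1e-12)


class TestMCA:
    def test_first_dimension_has_largest_inertia(self):
        panel, d, _ = _one_wave_binary_panel(n=800, seed=61)
        codes = panel.encoded(d)
        _, inertias = wb.mca_row_scores(codes)
        assert np.all(np.diff(inertias) <= 1e-12)

    def test_complement_recoding_preserves_row_scores(self):
        # 6-household toy: recoding an asset as its complement permutes the
        # two indicator columns, so the row scores are unchanged up to sign.
        # Brute-force check of the indicator algebra on the same toy.
        base = pd.DataFrame({
            "a": [1, 1, 1, 0, 0, 0],
            "b": [1, 1, 0, 1, 0, 0],
            "c": [1, 0, 1, 0, 1, 0],
        }, dtype=float)
        recoded = base.copy()
        recoded["b"] = 1.0 - base["b"]
        s0, _ = wb.mca_row_scores(base)
        s1, _ = wb.mca_row_scores(recoded)
        r = np.corrcoef(s0, s1)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        # brute force: explicit disjunctive matrix and residual SVD
        Z = np.column_stack([base[c] == v for c in base
                             for v in (0.0, 1.0)]).astype(float)
        P = Z / Z.sum()
        rmass, cmass = P.sum(axis=1), P.sum(axis=0)
        S = (P - np.outer(rmass, cmass)) / np.sqrt(np.outer(rmass, cmass))
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        brute = U[:, 0] * sv[0] / np.sqrt(rmass)
        assert np.allclose(np.abs(brute), np.abs(s0), atol=1e-10)

    def test_constant_column_dropped(self):
        codes = pd.DataFrame({
            "a": [1.0, 0.0, 1.0, 0.0],
            "b": [1.0, 1.0, 1.0, 1.0],
            "c": [1.0, 1.0, 0.0, 0.0],
        })
        scores, _ = wb.mca_row_scores(codes)
        assert len(scores) == 4


# ---------------------------------------------------------------------------
# report driver
# ---------------------------------------------------------------------------

def test_full_sensitivity_report_structure(bundle500):
    report = wb.run_sensitivity(
        bundle500["imputed"], bundle500["dictionary"], bundle500["scores"],
        assets=bundle500["model"].assets, modes=("asset", "wave"))
    assert len(report.asset_drops) == len(bundle500["model"].assets)
    assert len(report.wave_drops) == 5
    assert set(report.method_rhos) == set(wb.sensitivity.ALTERNATE_METHODS)
    minima = report.minima()
    assert all(-1 <= v <= 1 for v in minima.values() if np.isfinite(v))
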