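"""Cross-sectional comparison, congruence, construct validity, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wealthbridge as wb
from wealthbridge.validation import MIN_WAVE_N

from conftest import make_toy_panel


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert wb.spearman(x, x) == pytest.approx(1.0)
        assert wb.spearman(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # adjacent-swap pattern: d = (-1, 1, -1, 1, 0), sum d^2 = 4,
        # rho = 1 - 6*4/(5*(25-1)) = 1 - 24/120 = 0.8
        assert wb.spearman([1, 2, 3, 4, 5],
                           [2, 1, 4, 3, 5]) == pytest.approx(0.8, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wb.spearman([1, 2], [2, 1])
        with pytest.raises(ValueError):
            wb.spearman([1, 1, 1], [1, 2, 3])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariance_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        base = wb.spearman(x, y)
        assert wb.spearman(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert wb.spearman(x, y ** 3) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# Tucker congruence
# ---------------------------------------------------------------------------

class TestTucker:
    def test_identity_is_same(self):
        phi, label = wb.tucker_congruence([0.4, 0.7, 0.2], [0.4, 0.7, 0.2])
        assert phi == pytest.approx(1.0)
        assert label == "same"

    def test_orthogonal_is_low(self):
        phi, label = wb.tucker_congruence([1.0, 0.0], [0.0, 1.0])
        assert phi == pytest.approx(0.0)
        assert label == "low"

    @pytest.mark.parametrize("phi,expected", [
        (0.97, "same"), (0.95, "high"), (0.92, "high"),
        (0.90, "high"), (0.89, "moderate"), (0.85, "moderate"),
        (0.80, "low"),
    ])
    def test_category_cutpoints(self, phi, expected):
        # construct two unit vectors with exactly the desired cosine
        a = np.array([1.0, 0.0])
        b = np.array([phi, np.sqrt(1 - phi ** 2)])
        got_phi, label = wb.tucker_congruence(a, b)
        assert got_phi == pytest.approx(phi, abs=1e-12)
        assert label == expected

    def test_rescale_invariance_and_antisymmetry(self):
        a = np.array([0.3, -0.5, 0.8])
        b = np.array([0.2, -0.4, 0.9])
        phi, _ = wb.tucker_congruence(a, b)
        assert wb.tucker_congruence(3.7 * a, b)[0] == pytest.approx(phi)
        assert wb.tucker_congruence(a, 0.01 * b)[0] == pytest.approx(phi)
        assert wb.tucker_congruence(a, -b)[0] == pytest.approx(-phi)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            wb.tucker_congruence([0.0, 0.0], [1.0, 0.0])


# ---------------------------------------------------------------------------
# near-zero-variance filter
# ---------------------------------------------------------------------------

class TestNearZeroVariance:
    def _panel(self, tv, roof):
        n = len(tv)
        df = pd.DataFrame({
            "household_id": np.arange(n), "wave_id": 1, "year": 2000,
            "participation": True, "tv": tv, "roof": roof,
        })
        return wb.PanelDataset(data=df, asset_columns=["tv", "roof"])

    def test_prevalence_rule_on_binary(self):
        panel = self._panel([1] * 97 + [0] * 3, ["Low"] * 90 + ["High"] * 10)
        assert wb.near_zero_variance_filter(panel, 1, ["tv", "roof"]) == ["roof"]

    def test_binary_90_10_kept(self):
        panel = self._panel([1] * 90 + [0] * 10, ["Low"] * 50 + ["High"] * 50)
        kept = wb.near_zero_variance_filter(panel, 1, ["tv", "roof"])
        assert kept == ["tv", "roof"]

    def test_modal_share_rule_extends_to_ordinals(self):
        roof = ["Medium"] * 96 + ["Low"] * 2 + ["High"] * 2
        panel = self._panel([1] * 50 + [0] * 50, roof)
        assert wb.near_zero_variance_filter(panel, 1, ["tv", "roof"]) == ["tv"]

    def test_all_dropped_errors(self):
        panel = self._panel([1] * 99 + [0] * 1, ["Low"] * 99 + ["High"] * 1)
        with pytest.raises(ValueError):
            wb.near_zero_variance_filter(panel, 1, ["tv", "roof"])


# ---------------------------------------------------------------------------
# cross-sectional indices
# ---------------------------------------------------------------------------

class TestCrossSectional:
    def test_single_wave_cross_section_equals_harmonized(self):
        cfg = wb.SyntheticConfig(
            n_households=800, n_waves=1, wave_years=(1990,),
            secular_trend=(0.0,), dropout_probability=0.0, seed=23)
        panel, _ = wb.generate_panel(cfg)
        d = cfg.asset_dictionary()
        common = wb.select_common_assets(d, panel.waves)
        harmonized = wb.fit_harmonized_index(panel, d, assets=common)
        cross = wb.fit_cross_sectional_index(
            panel, d, wave=1, asset_set="harmonized-common",
            common_assets=common)
        assert np.allclose(harmonized.loadings, cross.loadings, atol=1e-10)
        phi, _ = wb.tucker_congruence(harmonized.loadings, cross.loadings)
        assert phi == pytest.approx(1.0, abs=1e-10)
        s_h = wb.score(harmonized, panel).table["score"]
        s_c = wb.score(cross, panel).table["score"]
        assert wb.spearman(s_h, s_c) == pytest.approx(1.0, abs=1e-12)

    def test_small_cell_suppressed(self, bundle500):
        out = wb.fit_cross_sectional_index(
            bundle500["imputed"], bundle500["dictionary"], wave=1,
            asset_set="harmonized-common", common_assets=bundle500["common"],
            min_n=10 ** 6)
        assert out is None

    def test_per_wave_rank_equivalence(self, bundle500):
        report = wb.validate_harmonized(
            bundle500["imputed"], bundle500["dictionary"],
            bundle500["model"], bundle500["scores"])
        assert (report.same_asset["rho"] >= 0.9).all()
        assert (report.all_asset["rho"] >= 0.9).all()
        assert (report.congruence["phi"] >= 0.9).all()


# ---------------------------------------------------------------------------
# construct validity
# ---------------------------------------------------------------------------

class TestConstructValidity:
    def test_variable_equal_to_score_gives_unity(self, bundle500):
        panel = bundle500["imputed"].copy()
        scores = bundle500["scores"]
        merged = panel.data.merge(
            scores.table[["household_id", "wave_id", "score"]],
            on=["household_id", "wave_id"], how="left")
        panel.data["self_score"] = merged["score"].to_numpy()
        table = wb.construct_validity(scores, panel, "self_score")
        ok = table.dropna(subset=["pearson_r"])
        assert np.allclose(ok["pearson_r"], 1.0, atol=1e-12)

    def test_recovers_schooling_correlation_scale(self, bundle500):
        table = wb.construct_validity(
            bundle500["scores"], bundle500["imputed"], "schooling")
        truth = bundle500["truth"]
        merged = bundle500["scores"].table.merge(
            truth.wealth, on=["household_id", "wave_id"])
        merged = merged.merge(
            truth.households[["household_id", "schooling"]], on="household_id")
        adults = set(bundle500["panel"].participants(
            bundle500["panel"].waves[-1])["household_id"])
        merged = merged[merged["household_id"].isin(adults)]
        for _, row in table.iterrows():
            cell = merged[merged["wave_id"] == row["wave_id"]]
            target = np.corrcoef(cell["schooling"], cell["w"])[0, 1]
            assert row["pearson_r"] > 0
            assert row["pearson_r"] == pytest.approx(target, abs=0.1)

    @pytest.mark.parametrize("rho_s", [-0.3, 0.3])
    def test_recovers_sign_of_schooling_correlation(self, rho_s):
        cfg = wb.SyntheticConfig(n_households=2000, seed=29,
                                 schooling_correlation=rho_s)
        full, truth = wb.generate_panel(cfg)
        panel = wb.apply_missingness(full, cfg, truth)
        d = cfg.asset_dictionary()
        common = wb.select_common_assets(d, panel.waves)
        imputed = wb.impute_missing(panel, common, d)
        model = wb.fit_harmonized_index(imputed, d, assets=common)
        scores = wb.score(model, imputed)
        table = wb.construct_validity(scores, imputed, "schooling")
        assert np.all(np.sign(table["pearson_r"]) == np.sign(rho_s))

    def test_independent_variable_near_zero(self, bundle500):
        rng = np.random.default_rng(0)
        panel = bundle500["imputed"].copy()
        panel.data["noise_var"] = rng.normal(size=len(panel.data))
        table = wb.construct_validity(bundle500["scores"], panel, "noise_var")
        for _, row in table.iterrows():
            assert abs(row["pearson_r"]) < 3 / np.sqrt(row["n"])

    def test_sparse_cells_reported_unavailable(self, bundle500):
        panel = bundle500["imputed"].copy()
        panel.data["mostly_missing"] = np.nan
        table = wb.construct_validity(
            bundle500["scores"], panel, "mostly_missing")
        assert table["pearson_r"].isna().all()


# ---------------------------------------------------------------------------
# distributional diagnostics
# ---------------------------------------------------------------------------

class TestDiagnostics:
    def test_identical_scores_fully_clumped(self):
        d = wb.diagnose_distribution(np.full(100, 1.3))
        assert d["clumping_fraction"] == pytest.approx(1 - 1 / 100)
        assert d["left_truncation"] and d["right_truncation"]

    def test_distinct_scores_not_clumped(self):
        d = wb.diagnose_distribution(np.linspace(-2, 2, 200))
        assert d["clumping_fraction"] == 0.0
        assert not d["left_truncation"] and not d["right_truncation"]

    def test_coarse_binary_index_is_clumped(self):
        rng = np.random.default_rng(33)
        # two binary assets -> at most 4 distinct index values
        scores = rng.choice([-1.2, -0.3, 0.4, 1.5], size=1000)
        d = wb.diagnose_distribution(scores)
        assert d["clumping_fraction"] >= 1 - 4 / 1000
        assert d["histogram"]["count"].sum() == 1000

    def test_minimum_sample_enforced(self):
        with pytest.raises(ValueError):
            wb.diagnose_distribution(np.arange(MIN_WAVE_N - 1))
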