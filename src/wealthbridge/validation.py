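"""Validation battery for the harmonized index.

Checks the harmonized index against standard cross-sectional practice: for
each wave, a cross-sectional index is fitted with the same machinery on that
wave alone — either with the same common-asset set (after deleting
zero-variance assets) or with all assets collected at the wave (after a
near-zero-variance filter) — and compared by Spearman rank correlation and
by the Tucker coefficient of congruence between loading vectors.  Construct
validity is assessed by Pearson correlation of the per-wave index with
schooling and anthropometry among households still present in adulthood.
Distributional diagnostics quantify clumping (tied index values) and flag
possible floor/ceiling truncation; a histogram export supports the visual
inspection the flags merely approximate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssetDictionary, PanelDataset
from .harmonize import IndexModel, WealthScore, fit_harmonized_index, score

logger = logging.getLogger("wealthbridge.validation")

NZV_THRESHOLD = 0.95   # modal-share cut (binary 95:5 prevalence ratio)
MIN_WAVE_N = 30        # cells below this are suppressed, not zeroed
TRUNCATION_MASS = 0.05  # share of households on one extreme distinct value

CONGRUENCE_LABELS = ("same", "high", "moderate", "low")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def spearman(x, y) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples required")
    if len(x) < 3:
        raise ValueError("need >= 3 pairs")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def tucker_congruence(loadings_a, loadings_b) -> tuple[float, str]:
    """Tucker coefficient of congruence between two loading vectors.

    phi = sum(a*b) / sqrt(sum(a^2) * sum(b^2)); labels follow the
    conventional cutpoints: same (> 0.95), high (0.90-0.95),
    moderate (0.85-0.89), low (< 0.85).
    """
    a = np.asarray(loadings_a, dtype=float)
    b = np.asarray(loadings_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 shared assets with matching shapes")
    na, nb = np.sqrt(np.sum(a * a)), np.sqrt(np.sum(b * b))
    if na == 0 or nb == 0:
        raise ValueError("zero loading vector")
    phi = float(np.sum(a * b) / (na * nb))
    if phi > 0.95:
        label = "same"
    elif phi >= 0.90:
        label = "high"
    elif phi >= 0.85:
        label = "moderate"
    else:
        label = "low"
    return phi, label


# ---------------------------------------------------------------------------
# per-wave machinery
# ---------------------------------------------------------------------------

def near_zero_variance_filter(panel: PanelDataset, wave,
                              assets: Sequence[str],
                              threshold: float = NZV_THRESHOLD) -> list[str]:
    """Drop assets whose modal category share exceeds the threshold at a wave."""
    rows = panel.participants(wave)
    if not len(rows):
        raise ValueError(f"wave {wave!r} has no participants")
    survivors = []
    for a in assets:
        observed = rows[a].dropna()
        if not len(observed):
            continue
        modal_share = observed.value_counts(normalize=True).iloc[0]
        if modal_share <= threshold:
            survivors.append(a)
        else:
            logger.info("near-zero-variance drop: %r at wave %r (share %.3f)",
                        a, wave, modal_share)
    if not survivors:
        raise ValueError(f"all assets near-zero-variance at wave {wave!r}")
    return survivors


def fit_cross_sectional_index(
    panel: PanelDataset,
    dictionary: AssetDictionary,
    wave,
    asset_set: str = "harmonized-common",
    common_assets: Sequence[str] | None = None,
    stratum: str | None = None,
    anchor: str | None = None,
    min_n: int = MIN_WAVE_N,
    continuous_handling: str = "polyserial",
) -> IndexModel | None:
    """Single-wave (optionally single-stratum) index with the same machinery.

    ``asset_set="harmonized-common"`` restricts to the harmonized common
    assets after deleting zero-variance ones; ``"all-available"`` uses every
    asset collected at the wave after the near-zero-variance filter.
    Returns None (with a log entry) when the cell has fewer than ``min_n``
    participants.
    """
    rows = panel.participants(wave)
    if stratum is not None:
        if "stratum" not in rows.columns:
            raise ValueError("panel has no stratum column")
        rows = rows[rows["stratum"] == stratum]
    if len(rows) < min_n:
        logger.info("skipping wave %r stratum %r: n=%d < %d",
                    wave, stratum, len(rows), min_n)
        return None
    sub = PanelDataset(
        data=rows.copy(),
        asset_columns=list(panel.asset_columns),
        extra_columns=list(panel.extra_columns),
    )
    if asset_set == "harmonized-common":
        if common_assets is None:
            raise ValueError("harmonized-common requires the common asset list")
        # delete zero-variance assets only
        assets = [a for a in common_assets
                  if sub.participants()[a].dropna().nunique() >= 2]
    elif asset_set == "all-available":
        collected = [a.name for a in dictionary
                     if wave in a.waves_collected and a.name in sub.data.columns]
        assets = near_zero_variance_filter(sub, wave, collected)
        assets = [a for a in assets
                  if sub.participants()[a].dropna().nunique() >= 2]
    else:
        raise ValueError("asset_set must be 'harmonized-common' or 'all-available'")
    if len(assets) < 2:
        logger.info("skipping wave %r stratum %r: <2 usable assets", wave, stratum)
        return None
    return fit_harmonized_index(
        sub, dictionary, assets=assets, anchor=anchor,
        continuous_handling=continuous_handling,
        provenance={"wave": wave, "stratum": stratum, "asset_set": asset_set},
    )


# ---------------------------------------------------------------------------
# construct validity & diagnostics
# ---------------------------------------------------------------------------

def construct_validity(
    scores: WealthScore,
    panel: PanelDataset,
    variable: str,
    waves: Sequence | None = None,
    adult_wave=None,
) -> pd.DataFrame:
    """Per-wave Pearson (and Spearman) correlation of an external variable
    with the harmonized score, among households that participated in
    adulthood (the last wave unless ``adult_wave`` is given).

    Cells with fewer than 3 complete pairs are reported unavailable (NaN).
    """
    if variable not in panel.data.columns:
        raise ValueError(f"variable {variable!r} not in panel")
    adult_wave = adult_wave if adult_wave is not None else panel.waves[-1]
    adults = set(panel.participants(adult_wave)["household_id"])
    waves = list(waves) if waves is not None else panel.waves
    merged = scores.table.merge(
        panel.data[["household_id", "wave_id", variable]],
        on=["household_id", "wave_id"], how="left")
    rows = []
    for wave in waves:
        cell = merged[(merged["wave_id"] == wave)
                      & merged["household_id"].isin(adults)]
        cell = cell.dropna(subset=["score", variable])
        n = len(cell)
        if n < 3 or cell[variable].nunique() < 2 or cell["score"].nunique() < 2:
            rows.append({"wave_id": wave, "variable": variable, "n": n,
                         "pearson_r": np.nan, "spearman_rho": np.nan})
            continue
        rows.append({
            "wave_id": wave, "variable": variable, "n": n,
            "pearson_r": float(stats.pearsonr(cell[variable],
                                              cell["score"]).statistic),
            "spearman_rho": spearman(cell[variable], cell["score"]),
        })
    return pd.DataFrame(rows)


def diagnose_distribution(scores_at_wave, n_bins: int = 30) -> dict:
    """Clumping fraction, truncation flags and histogram for one wave.

    clumping_fraction = 1 - (#distinct values)/(#households); a truncation
    flag fires at an end when the single most extreme distinct value holds
    more than 5% of households.  The flags are advisory; the histogram is
    emitted for the visual check they approximate.
    """
    s = np.asarray(scores_at_wave, dtype=float)
    if len(s) < MIN_WAVE_N:
        raise ValueError(f"need >= {MIN_WAVE_N} scores")
    distinct, counts = np.unique(s, return_counts=True)
    clumping = 1.0 - len(distinct) / len(s)
    left = counts[0] / len(s) > TRUNCATION_MASS
    right = counts[-1] / len(s) > TRUNCATION_MASS
    hist, edges = np.histogram(s, bins=n_bins)
    return {
        "clumping_fraction": float(clumping),
        "left_truncation": bool(left),
        "right_truncation": bool(right),
        "histogram": pd.DataFrame({
            "bin_left": edges[:-1], "bin_right": edges[1:], "count": hist,
        }),
    }


# ---------------------------------------------------------------------------
# report driver
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    same_asset: pd.DataFrame
    all_asset: pd.DataFrame
    stratified: pd.DataFrame
    congruence: pd.DataFrame
    construct: pd.DataFrame
    diagnostics: pd.DataFrame
    histograms: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "same_asset": self.same_asset.to_dict(orient="records"),
            "all_asset": self.all_asset.to_dict(orient="records"),
            "stratified": self.stratified.to_dict(orient="records"),
            "congruence": self.congruence.to_dict(orient="records"),
            "construct": self.construct.to_dict(orient="records"),
            "diagnostics": self.diagnostics.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _rho_over_common(benchmark: WealthScore, other: WealthScore) -> tuple[float, int]:
    merged = benchmark.table.merge(
        other.table, on=["household_id", "wave_id"], suffixes=("_a", "_b"))
    if len(merged) < 3:
        return np.nan, len(merged)
    return spearman(merged["score_a"], merged["score_b"]), len(merged)


def validate_harmonized(
    panel: PanelDataset,
    dictionary: AssetDictionary,
    model: IndexModel,
    scores: WealthScore,
    variables: Sequence[str] = ("schooling", "haz_24m", "bmi_adult"),
    strata: Sequence[str] | None = None,
    anchor: str | None = None,
    continuous_handling: str = "polyserial",
) -> ValidationReport:
    """Run the full validation battery against a fitted harmonized index."""
    waves = panel.waves
    common = model.assets
    same_rows, all_rows, strat_rows, cong_rows = [], [], [], []
    for wave in waves:
        cs = fit_cross_sectional_index(
            panel, dictionary, wave, "harmonized-common", common_assets=common,
            anchor=anchor, continuous_handling=continuous_handling)
        if cs is not None:
            cs_scores = score(cs, _wave_subset(panel, wave))
            rho, n = _rho_over_common(scores, cs_scores)
            same_rows.append({"wave_id": wave, "rho": rho, "n": n})
            shared = [a for a in common if a in cs.assets]
            phi, label = tucker_congruence(
                model.loadings_series()[shared],
                cs.loadings_series()[shared])
            cong_rows.append({"wave_id": wave, "phi": phi, "label": label,
                              "n_shared_assets": len(shared)})
        ca = fit_cross_sectional_index(
            panel, dictionary, wave, "all-available",
            anchor=anchor, continuous_handling=continuous_handling)
        if ca is not None:
            ca_scores = score(ca, _wave_subset(panel, wave))
            rho, n = _rho_over_common(scores, ca_scores)
            all_rows.append({"wave_id": wave, "rho": rho, "n": n})
        if strata:
            for st in strata:
                cst = fit_cross_sectional_index(
                    panel, dictionary, wave, "harmonized-common",
                    common_assets=common, stratum=st, anchor=anchor,
                    continuous_handling=continuous_handling)
                if cst is None:
                    continue
                st_panel = _wave_subset(panel, wave, stratum=st)
                st_scores = score(cst, st_panel)
                rho, n = _rho_over_common(scores, st_scores)
                strat_rows.append({"wave_id": wave, "stratum": st,
                                   "rho": rho, "n": n})

    construct_frames = [
        construct_validity(scores, panel, v)
        for v in variables if v in panel.data.columns
    ]
    diag_rows, histograms = [], {}
    per_wave = scores.per_wave()
    for wave in waves:
        s = per_wave.get(wave)
        if s is None or len(s) < MIN_WAVE_N:
            continue
        d = diagnose_distribution(s)
        histograms[wave] = d.pop("histogram")
        d["wave_id"] = wave
        diag_rows.append(d)

    return ValidationReport(
        same_asset=pd.DataFrame(same_rows),
        all_asset=pd.DataFrame(all_rows),
        stratified=pd.DataFrame(strat_rows),
        congruence=pd.DataFrame(cong_rows),
        construct=pd.concat(construct_frames, ignore_index=True)
        if construct_frames else pd.DataFrame(),
        diagnostics=pd.DataFrame(diag_rows),
        histograms=histograms,
    )


def _wave_subset(panel: PanelDataset, wave, stratum: str | None = None
                 ) -> PanelDataset:
    rows = panel.data[panel.data["wave_id"] == wave].copy()
    if stratum is not None:
        rows = rows[rows["stratum"] == stratum]
    return PanelDataset(
        data=rows,
        asset_columns=list(panel.asset_columns),
        extra_columns=list(panel.extra_columns),
    )
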