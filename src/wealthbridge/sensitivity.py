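"""Robustness ledger for the harmonized index.

Three families of checks, each compared to the benchmark index by Spearman
rank correlation over the household-waves scored under both:

* leave-out experiments — refitting after dropping each single asset, each
  single wave, and (optionally) each (asset, wave) pair;
* an inverse-wave-size weighted variant, where every pooled observation is
  weighted 1/n_wave so small waves count as much as large ones;
* alternate extraction procedures — PCA on the Pearson matrix of binarized
  indicators, single-factor EFA (iterated principal-axis) on either the
  mixed (polychoric) or the Pearson matrix, and MCA on the indicator matrix
  of the binarized data.

Binarization for the Pearson/MCA paths follows the convention: ordinal
variables are split top category vs the rest, crowding is split at 0.75
rooms per member, counts at the pooled median, and binary assets pass
through unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import Asset, AssetDictionary, PanelDataset
from .harmonize import (IndexModel, WealthScore, fit_harmonized_index, score,
                        select_common_assets)
from .mixedcorr import mixed_corr_matrix
from .validation import spearman

logger = logging.getLogger("wealthbridge.sensitivity")

CROWDING_BINARY_CUT = 0.75  # rooms per member; > cut codes as 1

ALTERNATE_METHODS = ("pca_pearson", "efa_polychoric", "efa_pearson", "mca")


def _rho_vs_benchmark(benchmark: WealthScore, other: WealthScore) -> float:
    merged = benchmark.table.merge(
        other.table, on=["household_id", "wave_id"], suffixes=("_a", "_b"))
    return spearman(merged["score_a"], merged["score_b"])


# ---------------------------------------------------------------------------
# leave-out experiments
# ---------------------------------------------------------------------------

def drop_robustness(
    panel: PanelDataset,
    dictionary: AssetDictionary,
    benchmark_scores: WealthScore,
    mode: str = "asset",
    assets: Sequence[str] | None = None,
    anchor: str | None = None,
    continuous_handling: str = "polyserial",
) -> pd.DataFrame:
    """Refit after dropping each asset / wave / (asset, wave) pair.

    Drops that would leave fewer than 2 assets or fewer than 2 waves are
    skipped with a log entry.
    """
    if mode not in ("asset", "wave", "joint"):
        raise ValueError("mode must be 'asset', 'wave' or 'joint'")
    waves = panel.waves
    assets = list(assets) if assets is not None else \
        select_common_assets(dictionary, waves)

    if mode == "asset":
        combos = [(a, None) for a in assets]
    elif mode == "wave":
        combos = [(None, w) for w in waves]
    else:
        combos = [(a, w) for a in assets for w in waves]

    rows = []
    for drop_asset, drop_wave in combos:
        keep_assets = [a for a in assets if a != drop_asset]
        keep_waves = [w for w in waves if w != drop_wave]
        if len(keep_assets) < 2 or (drop_wave is not None
                                    and len(keep_waves) < 2):
            logger.info("skipping drop (%r, %r): under-determined fit",
                        drop_asset, drop_wave)
            continue
        sub = panel
        if drop_wave is not None:
            sub = PanelDataset(
                data=panel.data[panel.data["wave_id"] != drop_wave].copy(),
                asset_columns=list(panel.asset_columns),
                extra_columns=list(panel.extra_columns),
            )
        model = fit_harmonized_index(
            sub, dictionary, assets=keep_assets, anchor=anchor,
            continuous_handling=continuous_handling,
            provenance={"dropped_asset": drop_asset, "dropped_wave": drop_wave})
        rho = _rho_vs_benchmark(benchmark_scores, score(model, sub))
        rows.append({"dropped_asset": drop_asset, "dropped_wave": drop_wave,
                     "rho": rho})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inverse-wave-size weighting
# ---------------------------------------------------------------------------

def weighted_variant(
    panel: PanelDataset,
    dictionary: AssetDictionary,
    benchmark_scores: WealthScore,
    assets: Sequence[str] | None = None,
    anchor: str | None = None,
    continuous_handling: str = "polyserial",
) -> tuple[IndexModel, float]:
    """Refit with observation weights 1/n_wave and compare to the benchmark."""
    rows = panel.participants()
    counts = rows["wave_id"].value_counts()
    weights = rows["wave_id"].map(lambda w: 1.0 / counts[w]).to_numpy()
    model = fit_harmonized_index(
        panel, dictionary, assets=assets, weights=weights, anchor=anchor,
        continuous_handling=continuous_handling,
        provenance={"weighting": "inverse_wave_size"})
    rho = _rho_vs_benchmark(benchmark_scores, score(model, panel))
    return model, rho


# ---------------------------------------------------------------------------
# binarization for alternate-method paths
# ---------------------------------------------------------------------------

def binarize_for_alternates(
    panel: PanelDataset, dictionary: AssetDictionary,
    assets: Sequence[str] | None = None,
) -> tuple[PanelDataset, AssetDictionary]:
    """Binarize every asset for the Pearson-matrix and MCA paths.

    Ordinals become 1 iff in the top category; crowding (continuous) becomes
    1 iff > 0.75 rooms per member; counts become 1 iff above the pooled
    median; binary assets are unchanged.
    """
    assets = list(assets) if assets is not None else list(panel.asset_columns)
    out = panel.copy()
    entries = []
    for name in assets:
        asset = dictionary[name]
        col = out.data[name]
        if asset.measurement_type == "binary":
            coded = dictionary.encode(col, name)
        elif asset.measurement_type == "ordinal":
            top = asset.categories[-1]
            coded = col.map(
                lambda v, top=top, k=len(asset.categories):
                np.nan if pd.isna(v) else float(v == top or v == k - 1))
        elif asset.measurement_type == "continuous":
            vals = pd.to_numeric(col, errors="raise")
            coded = (vals > CROWDING_BINARY_CUT).astype(float).where(vals.notna())
        else:  # count
            vals = pd.to_numeric(col, errors="raise")
            med = vals[out.data["participation"].astype(bool)].median()
            coded = (vals > med).astype(float).where(vals.notna())
        out.data[name] = coded
        entries.append(Asset(name, "binary", asset.waves_collected, (0, 1),
                             asset.orientation_hint))
    binary_dict = AssetDictionary(entries)
    return out, binary_dict


# ---------------------------------------------------------------------------
# alternate extraction procedures
# ---------------------------------------------------------------------------

def principal_axis_factoring(corr: np.ndarray, tol: float = 1e-6,
                             max_iter: int = 100) -> tuple[np.ndarray, bool]:
    """Single-factor iterated principal-axis loadings.

    Communalities start at squared multiple correlations, replace the
    diagonal, and are re-estimated from the leading eigenpair until they
    change by less than ``tol``.  Heywood communalities (> 1) are clamped to
    1 and flagged.
    """
    p = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
        h2 = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        h2 = np.max(np.abs(corr - np.eye(p)), axis=1) ** 2
    h2 = np.clip(h2, 0.0, 1.0)
    heywood = False
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        vals, vecs = np.linalg.eigh(reduced)
        lead = int(np.argmax(vals))
        load = vecs[:, lead] * np.sqrt(max(vals[lead], 0.0))
        new_h2 = load ** 2
        if np.any(new_h2 > 1.0):
            heywood = True
            new_h2 = np.clip(new_h2, 0.0, 1.0)
            load = np.sign(load) * np.sqrt(new_h2)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    if heywood:
        logger.warning("Heywood case in principal-axis factoring; clamped")
    return load, heywood


def mca_row_scores(indicator_data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """First-dimension row scores of a multiple correspondence analysis.

    Builds the full disjunctive (indicator) matrix over the binary columns,
    drops constant categories, and takes the SVD of the standardized residual
    matrix S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}; row principal coordinates
    on the first dimension are returned together with all principal inertias.
    """
    cols = []
    for name in indicator_data.columns:
        v = indicator_data[name].to_numpy(dtype=float)
        for level in (0.0, 1.0):
            ind = (v == level).astype(float)
            if ind.sum() in (0, len(ind)):
                logger.info("MCA: dropping constant category %s=%g", name, level)
                continue
            cols.append(ind)
    if len(cols) < 2:
        raise ValueError("MCA needs at least two non-constant categories")
    Z = np.column_stack(cols)
    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    # first singular dimension of the residual matrix
    row_scores = U[:, 0] * sv[0] / np.sqrt(r)
    return row_scores, sv ** 2


def alternate_extraction(
    panel: PanelDataset,
    dictionary: AssetDictionary,
    benchmark_scores: WealthScore,
    method: str,
    assets: Sequence[str] | None = None,
    anchor: str | None = None,
) -> tuple[IndexModel | None, float]:
    """Score the panel with an alternate extraction and compare by Spearman.

    pca_pearson / efa_pearson / mca operate on the binarized panel;
    efa_polychoric reuses the mixed correlation matrix of the raw codes.
    Returns the fitted model (None for MCA, which has no loading-vector
    model of the same shape) and the rank correlation with the benchmark.
    """
    if method not in ALTERNATE_METHODS:
        raise ValueError(f"unknown method {method!r}")
    assets = list(assets) if assets is not None else \
        select_common_assets(dictionary, panel.waves)
    anchor_asset = anchor
    if anchor_asset is None:
        hinted = [a for a in assets
                  if dictionary[a].orientation_hint == "positive"]
        anchor_asset = hinted[0] if hinted else assets[0]

    if method == "efa_polychoric":
        work_panel, work_dict = panel, dictionary
    else:
        work_panel, work_dict = binarize_for_alternates(panel, dictionary, assets)

    rows = work_panel.participants()
    codes = work_panel.encoded(work_dict, assets)
    X = codes.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("alternate extraction requires an imputed panel")

    if method == "mca":
        raw, _ = mca_row_scores(codes)
        anchor_vals = X[:, assets.index(anchor_asset)]
        if np.corrcoef(anchor_vals, raw)[0, 1] < 0:
            raw = -raw
        table = rows[["household_id", "wave_id", "year"]].copy()
        table["score"] = (raw - raw.mean()) / raw.std()
        alt_scores = WealthScore(table=table.reset_index(drop=True))
        return None, _rho_vs_benchmark(benchmark_scores, alt_scores)

    if method == "pca_pearson":
        corr = np.corrcoef(X, rowvar=False)
        vals, vecs = np.linalg.eigh(corr)
        lead = int(np.argmax(vals))
        loadings = vecs[:, lead] * np.sqrt(max(vals[lead], 0.0))
        variance = 100.0 * vals[lead] / np.trace(corr)
    else:  # efa_polychoric / efa_pearson
        if method == "efa_polychoric":
            corr = mixed_corr_matrix(work_panel, work_dict, assets=assets).rho
        else:
            corr = np.corrcoef(X, rowvar=False)
        loadings, _ = principal_axis_factoring(corr)
        variance = 100.0 * float(np.sum(loadings ** 2)) / corr.shape[0]

    if loadings[assets.index(anchor_asset)] < 0:
        loadings = -loadings
    means, sds = X.mean(axis=0), X.std(axis=0)
    raw = ((X - means) / sds) @ loadings
    model = IndexModel(
        assets=assets,
        loadings=loadings,
        variance_explained_pct=float(variance),
        anchor_asset=anchor_asset,
        anchor_sign=1.0,
        asset_means=means,
        asset_sds=sds,
        score_mean=float(raw.mean()),
        score_sd=float(raw.std()),
        categories={a: (list(work_dict[a].categories)
                        if work_dict[a].categories else None) for a in assets},
        measurement_types={a: work_dict[a].measurement_type for a in assets},
        provenance={"extraction": method},
    )
    alt_scores = score(model, work_panel)
    return model, _rho_vs_benchmark(benchmark_scores, alt_scores)


# ---------------------------------------------------------------------------
# report driver
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    asset_drops: pd.DataFrame
    wave_drops: pd.DataFrame
    joint_drops: pd.DataFrame
    weighted_rho: float
    method_rhos: dict = field(default_factory=dict)

    def minima(self) -> dict:
        out = {}
        for name, table in (("asset_drops", self.asset_drops),
                            ("wave_drops", self.wave_drops),
                            ("joint_drops", self.joint_drops)):
            if len(table):
                out[name] = float(table["rho"].min())
        out["weighted"] = self.weighted_rho
        out.update({f"method_{k}": v for k, v in self.method_rhos.items()})
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "asset_drops": self.asset_drops.to_dict(orient="records"),
            "wave_drops": self.wave_drops.to_dict(orient="records"),
            "joint_drops": self.joint_drops.to_dict(orient="records"),
            "weighted_rho": self.weighted_rho,
            "method_rhos": self.method_rhos,
            "minima": self.minima(),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_sensitivity(
    panel: PanelDataset,
    dictionary: AssetDictionary,
    benchmark_scores: WealthScore,
    assets: Sequence[str] | None = None,
    anchor: str | None = None,
    modes: Sequence[str] = ("asset", "wave"),
    methods: Sequence[str] = ALTERNATE_METHODS,
    weighted: bool = True,
    continuous_handling: str = "polyserial",
) -> SensitivityReport:
    """Run the configured robustness experiments against a benchmark."""
    empty = pd.DataFrame(columns=["dropped_asset", "dropped_wave", "rho"])
    tables = {"asset": empty, "wave": empty, "joint": empty}
    for mode in modes:
        tables[mode] = drop_robustness(
            panel, dictionary, benchmark_scores, mode=mode, assets=assets,
            anchor=anchor, continuous_handling=continuous_handling)
    w_rho = np.nan
    if weighted:
        _, w_rho = weighted_variant(
            panel, dictionary, benchmark_scores, assets=assets, anchor=anchor,
            continuous_handling=continuous_handling)
    method_rhos = {}
    for m in methods:
        _, method_rhos[m] = alternate_extraction(
            panel, dictionary, benchmark_scores, m, assets=assets, anchor=anchor)
    return SensitivityReport(
        asset_drops=tables["asset"],
        wave_drops=tables["wave"],
        joint_drops=tables["joint"],
        weighted_rho=float(w_rho),
        method_rhos=method_rhos,
    )
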