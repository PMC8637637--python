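"""Temporally-harmonized wealth index: asset selection, imputation, pooled
first-principal-component fit, and scoring.

The harmonized index is the first principal component of the mixed-type
(polychoric) correlation matrix computed after pooling every participating
household-wave as one observation row.  Eligible assets are those collected
at every wave or missing from at most one wave.  Missing eligible-asset
values for participants are imputed by carrying the household's preceding
wave forward when it participated there, otherwise by the wave's
cross-sectional mode (ties broken toward the lower, less wealthy category).

Because PCA eigenvector signs are arbitrary, the component is oriented so a
configured anchor asset (by default the first asset flagged
orientation_hint="positive", typically television/refrigerator) carries a
nonnegative loading.  Scores are the loading-weighted sum of pooled z-scored
integer codes, affinely standardized so the pooled fitting sample has mean 0
and SD 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import AssetDictionary, PanelDataset
from .mixedcorr import MixedCorrelationMatrix, mixed_corr_matrix

logger = logging.getLogger("wealthbridge.harmonize")


# ---------------------------------------------------------------------------
# asset eligibility
# ---------------------------------------------------------------------------

def select_common_assets(dictionary: AssetDictionary, waves: Sequence) -> list[str]:
    """Assets collected at every wave or missing from at most one wave."""
    waves = list(waves)
    if not waves:
        raise ValueError("waves must be nonempty")
    selected = [
        a.name for a in dictionary
        if len(set(waves) - set(a.waves_collected)) <= 1
    ]
    if not selected:
        raise ValueError("no asset satisfies the harmonization eligibility rule")
    return selected


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def _mode_lowest(values: pd.Series, order: dict | None = None):
    """Most frequent value; ties broken toward the lowest category.

    ``order`` maps category labels to their rank; without it values sort
    natively (fine for numeric codes).
    """
    counts = values.value_counts()
    top = counts[counts == counts.max()]
    key = (lambda v: order.get(v, v)) if order else None
    return sorted(top.index, key=key)[0]


def impute_missing(panel: PanelDataset, assets: Sequence[str],
                   dictionary: AssetDictionary | None = None) -> PanelDataset:
    """Two-rule imputation over participating household-waves.

    Rule 1 (carry-forward): a participant missing asset a at wave t takes the
    household's wave t-1 value if it participated then and the value exists.
    Rule 2 (cross-sectional mode): otherwise the mode of a among wave-t
    participants.  If a wave has no observed value of the asset at all, the
    nearest earlier wave's mode is used (logged).  Non-participant rows are
    untouched.  A boolean imputation-provenance frame is attached to the
    returned panel.
    """
    out = panel.copy()
    df = out.data.sort_values(["household_id", "wave_id"]).reset_index(drop=True)
    assets = list(assets)
    waves = out.waves
    flags = pd.DataFrame(False, index=df.index, columns=assets)
    part = df["participation"].astype(bool)

    orders: dict[str, dict | None] = {}
    for a in assets:
        cats = dictionary[a].categories if (
            dictionary is not None and a in dictionary) else None
        orders[a] = {c: i for i, c in enumerate(cats)} if cats else None

    wave_modes: dict[tuple, object] = {}
    for wi, wave in enumerate(waves):
        at_wave = part & (df["wave_id"] == wave)
        for a in assets:
            observed = df.loc[at_wave, a].dropna()
            if len(observed):
                wave_modes[(wave, a)] = _mode_lowest(observed, orders[a])
            else:
                for earlier in reversed(waves[:wi]):
                    if (earlier, a) in wave_modes:
                        wave_modes[(wave, a)] = wave_modes[(earlier, a)]
                        logger.info(
                            "asset %r unobserved at wave %r; using wave %r mode",
                            a, wave, earlier)
                        break

    # wave-by-wave so that carry-forward can chain through imputed values
    for wi, wave in enumerate(waves):
        here = part.to_numpy() & (df["wave_id"] == wave).to_numpy()
        if wi > 0:
            prev_rows = df[df["wave_id"] == waves[wi - 1]].set_index("household_id")
        for a in assets:
            missing = here & df[a].isna().to_numpy()
            if not missing.any():
                continue
            fill = pd.Series(np.nan, index=df.index[missing], dtype=object)
            if wi > 0:
                hh_missing = df.loc[missing, "household_id"]
                prev_part = prev_rows["participation"].reindex(hh_missing)
                prev_val = prev_rows[a].reindex(hh_missing)
                usable = prev_part.fillna(False).astype(bool) & prev_val.notna()
                fill[usable.to_numpy()] = prev_val[usable.to_numpy()].to_numpy()
            mode = wave_modes.get((wave, a))
            if fill.isna().any() and mode is None:
                raise ValueError(
                    f"asset {a!r} has no observed value at or before "
                    f"wave {wave!r}")
            fill = fill.where(fill.notna(), mode)
            vals = fill.to_numpy()
            if pd.api.types.is_numeric_dtype(df[a]):
                vals = vals.astype(float)
            df.loc[missing, a] = vals
            flags.loc[df.index[missing], a] = True
    n_imp = int(flags.to_numpy().sum())
    if n_imp:
        logger.info("imputed %d participant cells across %d assets",
                    n_imp, len(assets))
    out.data = df
    out.imputation_flags = flags
    return out


# ---------------------------------------------------------------------------
# index model
# ---------------------------------------------------------------------------

@dataclass
class IndexModel:
    """First-principal-component wealth index fitted on pooled waves.

    Loadings are the leading eigenvector of the mixed correlation matrix
    scaled by the square root of its eigenvalue; ``variance_explained_pct``
    is that eigenvalue's share of the matrix trace.  ``asset_means`` /
    ``asset_sds`` standardize the integer-coded asset values and
    ``score_mean`` / ``score_sd`` standardize the raw weighted sums so the
    pooled fitting sample scores have mean 0 and SD 1.
    """

    assets: list[str]
    loadings: np.ndarray
    variance_explained_pct: float
    anchor_asset: str
    anchor_sign: float
    asset_means: np.ndarray
    asset_sds: np.ndarray
    score_mean: float
    score_sd: float
    categories: dict[str, list | None]
    measurement_types: dict[str, str]
    provenance: dict = field(default_factory=dict)
    correlation: MixedCorrelationMatrix | None = None

    def loadings_series(self) -> pd.Series:
        return pd.Series(self.loadings, index=self.assets, name="loading")

    def loadings_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "asset": self.assets,
            "loading": np.round(self.loadings, 4),
        })

    def to_json(self, path=None) -> str:
        payload = {
            "assets": self.assets,
            "loadings": [float(v) for v in self.loadings],
            "variance_explained_pct": self.variance_explained_pct,
            "anchor_asset": self.anchor_asset,
            "anchor_sign": self.anchor_sign,
            "asset_means": [float(v) for v in self.asset_means],
            "asset_sds": [float(v) for v in self.asset_sds],
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "categories": {k: (list(v) if v is not None else None)
                           for k, v in self.categories.items()},
            "measurement_types": self.measurement_types,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "IndexModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls(
            assets=payload["assets"],
            loadings=np.asarray(payload["loadings"], float),
            variance_explained_pct=payload["variance_explained_pct"],
            anchor_asset=payload["anchor_asset"],
            anchor_sign=payload["anchor_sign"],
            asset_means=np.asarray(payload["asset_means"], float),
            asset_sds=np.asarray(payload["asset_sds"], float),
            score_mean=payload["score_mean"],
            score_sd=payload["score_sd"],
            categories=payload["categories"],
            measurement_types=payload["measurement_types"],
            provenance=payload.get("provenance", {}),
        )


def _pick_anchor(dictionary: AssetDictionary, assets: Sequence[str],
                 anchor: str | None) -> str:
    if anchor is not None:
        if anchor not in assets:
            raise ValueError(f"anchor asset {anchor!r} not among fitted assets")
        return anchor
    for name in assets:
        if dictionary[name].orientation_hint == "positive":
            return name
    return assets[0]


def fit_harmonized_index(
    panel: PanelDataset,
    dictionary: AssetDictionary,
    assets: Sequence[str] | None = None,
    weights=None,
    anchor: str | None = None,
    continuous_handling: str = "polyserial",
    provenance: dict | None = None,
) -> IndexModel:
    """Fit the pooled-wave first principal component on the mixed matrix.

    ``weights`` are optional per-row observation weights over the pooled
    participant rows (ordered as ``panel.participants()``).
    """
    assets = list(assets) if assets is not None else \
        select_common_assets(dictionary, panel.waves)
    corr = mixed_corr_matrix(panel, dictionary, weights=weights, assets=assets,
                             continuous_handling=continuous_handling)
    assets = corr.assets  # degenerate assets may have been excluded
    if len(assets) < 2:
        raise ValueError("fewer than 2 assets survive; no index possible")

    vals, vecs = np.linalg.eigh(corr.rho)
    lead = int(np.argmax(vals))
    eigval = float(vals[lead])
    loadings = vecs[:, lead] * np.sqrt(max(eigval, 0.0))
    variance_explained = 100.0 * eigval / float(np.trace(corr.rho))

    anchor_asset = _pick_anchor(dictionary, assets, anchor)
    sign = 1.0
    if loadings[assets.index(anchor_asset)] < 0:
        sign = -1.0
        loadings = -loadings

    codes = panel.encoded(dictionary, assets)
    X = codes.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("panel must be imputed before fitting (missing codes)")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if np.any(sds <= 0):
        raise ValueError("zero-variance asset slipped through exclusion")
    raw = ((X - means) / sds) @ loadings
    model = IndexModel(
        assets=assets,
        loadings=loadings,
        variance_explained_pct=variance_explained,
        anchor_asset=anchor_asset,
        anchor_sign=sign,
        asset_means=means,
        asset_sds=sds,
        score_mean=float(raw.mean()),
        score_sd=float(raw.std()),
        categories={a: (list(dictionary[a].categories)
                        if dictionary[a].categories else None)
                    for a in assets},
        measurement_types={a: dictionary[a].measurement_type for a in assets},
        provenance=dict(provenance or {},
                        waves=list(panel.waves),
                        weighted=weights is not None,
                        extraction="pca_mixed"),
        correlation=corr,
    )
    return model


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class WealthScore:
    """Standardized index values per participating household-wave."""

    table: pd.DataFrame  # household_id, wave_id, year, score

    def per_wave(self) -> dict:
        return {w: g["score"].to_numpy()
                for w, g in self.table.groupby("wave_id", sort=True)}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def score(model: IndexModel, panel: PanelDataset,
          dictionary: AssetDictionary | None = None) -> WealthScore:
    """Score participating household-waves with a fitted index.

    Asset values are mapped to integer codes with the model's stored category
    orders, z-scored with the model's pooled constants, combined with the
    loadings, and standardized by the model's pooled score mean/SD.
    """
    rows = panel.participants()
    missing = [a for a in model.assets if a not in rows.columns]
    if missing:
        raise ValueError(f"panel lacks model assets {missing}")
    Z = np.empty((len(rows), len(model.assets)))
    for j, a in enumerate(model.assets):
        cats = model.categories.get(a)
        vals = rows[a]
        if cats is not None:
            mapping = {c: float(i) for i, c in enumerate(cats)}
            for i in range(len(cats)):
                mapping.setdefault(i, float(i))
                mapping.setdefault(float(i), float(i))
                mapping.setdefault(str(i), float(i))
            coded = vals.map(mapping)
            unknown = vals.notna() & coded.isna()
            if unknown.any():
                raise ValueError(
                    f"asset {a!r}: unseen category {vals[unknown].iloc[0]!r}")
            coded = coded.to_numpy(dtype=float)
        else:
            coded = pd.to_numeric(vals, errors="raise").to_numpy(dtype=float)
        if np.isnan(coded).any():
            raise ValueError(f"asset {a!r}: missing values in scoring panel")
        Z[:, j] = (coded - model.asset_means[j]) / model.asset_sds[j]
    raw = Z @ model.loadings
    standardized = (raw - model.score_mean) / model.score_sd
    table = rows[["household_id", "wave_id", "year"]].copy()
    table["score"] = standardized
    return WealthScore(table=table.reset_index(drop=True))


def summarize_by_wave(scores: WealthScore) -> pd.DataFrame:
    """Per-wave mean +/- SD and median [IQR] of the index, in wave order."""
    if not len(scores.table):
        raise ValueError("empty scores")
    rows = []
    for wave, g in scores.table.groupby("wave_id", sort=True):
        s = g["score"].to_numpy()
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        rows.append({
            "wave_id": wave,
            "year": g["year"].iloc[0],
            "n": len(s),
            "mean": s.mean(),
            "sd": s.std(ddof=1) if len(s) > 1 else 0.0,
            "median": med,
            "iqr_low": q1,
            "iqr_high": q3,
        })
    out = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    return out
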