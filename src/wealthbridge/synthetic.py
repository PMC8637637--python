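"""Synthetic longitudinal asset panels with known latent wealth.

The generator emulates the structure of LMIC birth-cohort asset data: a
household-level latent wealth trajectory

    w_ht = alpha_h + beta_h * (t - t1) + delta_t + eps_ht

(alpha_h a household random intercept, beta_h a random slope over wave index,
delta_t an additive secular trend in wave-1 SD units, eps_ht occasion noise),
observed only through thresholded indicators: a binary asset j is owned when

    lambda_j * w_ht + sqrt(1 - lambda_j^2) * u > tau_jt ,

ordinal assets use K-1 ordered thresholds the same way, and a continuous
rooms-per-member crowding variable is an affine map of its latent value.
Negative loadings (radio, livestock) reproduce assets whose ownership falls
as wealth rises.  Wave-declining thresholds give asset diffusion; per-wave
dropout (MCAR or wealth-dependent MAR) gives attrition.  Household schooling
is generated correlated with the latent intercept for construct-validity
checks; urban/rural stratum and haz/BMI columns are optional extras.

Seeding: a single master seed feeds ``numpy.random.SeedSequence``; child
streams are spawned in a fixed documented order (household effects, occasion
noise, binary latents, ordinal latents, crowding, schooling, externals,
attrition), so every draw is reproducible and adding streams never perturbs
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Asset, AssetDictionary, PanelDataset

_STREAMS = ("household", "residual", "binary", "ordinal", "crowding",
            "schooling", "external", "attrition")

#: crowding affine map: rooms = clip(0.75 + 0.35 * latent, 0.05, 2.0),
#: centred on the 0.75 rooms-per-member binarization cut so roughly half of
#: households fall on each side, with values in (0, 2].
CROWDING_CENTER = 0.75
CROWDING_SLOPE = 0.35
CROWDING_MIN = 0.05
CROWDING_MAX = 2.0

ORDINAL_LABELS = ("Low", "Medium", "High")


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe a five-wave cohort of 2000 households observed over
    roughly three decades with 12 indicators: ten binary assets (two with
    negative loadings, emulating radio/livestock), one ordinal Low/Medium/High
    housing-quality variable and one continuous rooms-per-member crowding
    variable, rising mean wealth (positive secular trend), asset diffusion
    (falling thresholds) and 10% per-wave monotone attrition.
    """

    n_households: int = 2000
    n_waves: int = 5
    wave_years: tuple = (1990, 1997, 2004, 2011, 2018)
    n_binary_assets: int = 10
    n_ordinal_assets: int = 1
    loading_vector: tuple = (
        0.80, 0.75, 0.70, 0.65, 0.60, 0.55, 0.70, 0.60, -0.50, -0.55,  # binary
        0.70,                                                          # ordinal
    )
    secular_trend: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)  # delta_t, SD units
    sigma_alpha: float = 0.8
    mu_beta: float = 0.0
    sigma_beta: float = 0.05
    sigma_eps: float = 0.6
    threshold_schedule: np.ndarray | None = None  # (n_bin+n_ord*(K-1), n_waves)
    ordinal_categories: int = 3
    crowding_loading: float = 0.6
    include_crowding: bool = True
    schooling_correlation: float = 0.5
    haz_correlation: float = 0.3
    bmi_correlation: float = 0.2
    urban_fraction: float = 0.6
    dropout_probability: float = 0.10
    attrition_mechanism: str = "MCAR"  # or "MAR"
    mar_coefficient: float = 0.0  # added to logit(dropout) per SD of wealth
    monotone_attrition: bool = True
    missing_asset_plan: tuple = ()  # (asset_name, wave_id) pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households <= 0 or self.n_waves <= 0:
            raise ValueError("n_households and n_waves must be positive")
        years = tuple(self.wave_years)[: self.n_waves]
        if len(years) != self.n_waves or any(
            b <= a for a, b in zip(years, years[1:])
        ):
            raise ValueError("wave_years must be strictly increasing, one per wave")
        self.wave_years = years
        lam = np.asarray(self.loading_vector, dtype=float)
        if len(lam) != self.n_binary_assets + self.n_ordinal_assets:
            raise ValueError("loading_vector length must equal binary+ordinal assets")
        if np.any(np.abs(lam) > 1) or abs(self.crowding_loading) > 1 or \
                abs(self.schooling_correlation) > 1:
            raise ValueError("loadings and correlations must lie in [-1, 1]")
        if not 0 <= self.dropout_probability <= 1:
            raise ValueError("dropout_probability must lie in [0, 1]")
        if self.attrition_mechanism not in ("MCAR", "MAR"):
            raise ValueError("attrition_mechanism must be MCAR or MAR")
        self.secular_trend = tuple(self.secular_trend)[: self.n_waves]
        if len(self.secular_trend) != self.n_waves:
            raise ValueError("secular_trend needs one entry per wave")
        if self.threshold_schedule is None:
            self.threshold_schedule = self.default_threshold_schedule()
        else:
            self.threshold_schedule = np.asarray(self.threshold_schedule, float)
            if not np.all(np.isfinite(self.threshold_schedule)):
                raise ValueError("thresholds must be finite")

    # -- derived layout ---------------------------------------------------

    @property
    def asset_names(self) -> list[str]:
        names = [f"asset_{i+1:02d}" for i in range(self.n_binary_assets)]
        names += [f"housing_{i+1}" for i in range(self.n_ordinal_assets)]
        if self.include_crowding:
            names.append("crowding")
        return names

    @property
    def wave_ids(self) -> list[int]:
        return list(range(1, self.n_waves + 1))

    def default_threshold_schedule(self) -> np.ndarray:
        """Per-asset, per-wave thresholds in latent SD units.

        Binary assets get bases spread over [-0.3, 1.2]; positively-loaded
        assets additionally diffuse (threshold falls 0.05 SD per wave).
        Ordinal variables get fixed cuts at -0.4 and +0.6 between the K=3
        categories (extended evenly for larger K).
        """
        lam = np.asarray(self.loading_vector, float)
        rows = []
        bases = np.linspace(-0.3, 1.2, max(self.n_binary_assets, 1))
        t = np.arange(self.n_waves)
        for j in range(self.n_binary_assets):
            drift = -0.05 if lam[j] > 0 else 0.0
            rows.append(bases[j] + drift * t)
        k = self.ordinal_categories
        cuts = np.linspace(-0.4, 0.6, k - 1)
        for _ in range(self.n_ordinal_assets):
            for c in cuts:
                rows.append(np.full(self.n_waves, c))
        return np.asarray(rows)

    def asset_dictionary(self) -> AssetDictionary:
        waves = tuple(self.wave_ids)
        lam = np.asarray(self.loading_vector, float)
        plan: dict[str, set] = {}
        for name, wave in self.missing_asset_plan:
            plan.setdefault(name, set()).add(wave)
        entries = []
        for j in range(self.n_binary_assets):
            name = f"asset_{j+1:02d}"
            collected = tuple(w for w in waves if w not in plan.get(name, ()))
            hint = "positive" if lam[j] > 0 else "negative"
            entries.append(Asset(name, "binary", collected, (0, 1), hint))
        labels = tuple(ORDINAL_LABELS[: self.ordinal_categories]) \
            if self.ordinal_categories <= 3 else tuple(
                f"level_{i}" for i in range(self.ordinal_categories))
        for i in range(self.n_ordinal_assets):
            name = f"housing_{i+1}"
            collected = tuple(w for w in waves if w not in plan.get(name, ()))
            entries.append(Asset(name, "ordinal", collected, labels, "positive"))
        if self.include_crowding:
            collected = tuple(w for w in waves if w not in plan.get("crowding", ()))
            entries.append(Asset("crowding", "continuous", collected, None,
                                 "positive" if self.crowding_loading >= 0
                                 else "negative"))
        return AssetDictionary(entries)


@dataclass
class LatentTruth:
    """Ground truth behind a generated panel."""

    wealth: pd.DataFrame  # household_id, wave_id, w
    households: pd.DataFrame  # household_id, alpha, beta, schooling, stratum

    def to_csv(self, wealth_path, households_path) -> None:
        self.wealth.to_csv(wealth_path, index=False)
        self.households.to_csv(households_path, index=False)


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_panel(config: SyntheticConfig) -> tuple[PanelDataset, LatentTruth]:
    """Draw a complete (pre-attrition) panel plus its latent truth."""
    rngs = _child_rngs(config.seed)
    n, T = config.n_households, config.n_waves
    lam = np.asarray(config.loading_vector, float)

    alpha = rngs["household"].normal(0.0, config.sigma_alpha, n)
    beta = rngs["household"].normal(config.mu_beta, config.sigma_beta, n)
    eps = rngs["residual"].normal(0.0, config.sigma_eps, (n, T))
    t_idx = np.arange(T)
    delta = np.asarray(config.secular_trend)
    w = alpha[:, None] + beta[:, None] * t_idx[None, :] + delta[None, :] + eps

    columns: dict[str, np.ndarray] = {}
    tau = config.threshold_schedule
    for j in range(config.n_binary_assets):
        u = rngs["binary"].normal(size=(n, T))
        latent = lam[j] * w + np.sqrt(1.0 - lam[j] ** 2) * u
        columns[f"asset_{j+1:02d}"] = (latent > tau[j][None, :]).astype(int)
    k = config.ordinal_categories
    labels = config.asset_dictionary()
    for i in range(config.n_ordinal_assets):
        lj = lam[config.n_binary_assets + i]
        u = rngs["ordinal"].normal(size=(n, T))
        latent = lj * w + np.sqrt(1.0 - lj ** 2) * u
        cuts = tau[config.n_binary_assets + i * (k - 1):
                   config.n_binary_assets + (i + 1) * (k - 1)]
        codes = np.zeros((n, T), dtype=int)
        for c in cuts:
            codes += latent > c[None, :]
        cats = labels[f"housing_{i+1}"].categories
        columns[f"housing_{i+1}"] = np.asarray(cats, object)[codes]
    if config.include_crowding:
        g = config.crowding_loading
        v = rngs["crowding"].normal(size=(n, T))
        latent = g * w + np.sqrt(1.0 - g ** 2) * v
        columns["crowding"] = np.clip(
            CROWDING_CENTER + CROWDING_SLOPE * latent, CROWDING_MIN, CROWDING_MAX
        ).round(3)

    rho_s = config.schooling_correlation
    z = rngs["schooling"].normal(size=n)
    s_latent = rho_s * (alpha / config.sigma_alpha) + np.sqrt(1 - rho_s ** 2) * z
    schooling = np.clip(np.round(6 + 3 * s_latent), 0, 18).astype(int)

    ext = rngs["external"]
    a_std = alpha / config.sigma_alpha
    haz = (config.haz_correlation * a_std
           + np.sqrt(1 - config.haz_correlation ** 2) * ext.normal(size=n) - 1.0)
    bmi = (24 + 3 * (config.bmi_correlation * a_std
                     + np.sqrt(1 - config.bmi_correlation ** 2)
                     * ext.normal(size=n)))
    # urban residence mildly predicted by the latent intercept
    stratum_latent = 0.4 * a_std + np.sqrt(1 - 0.4 ** 2) * ext.normal(size=n)
    cut = stats.norm.ppf(1 - config.urban_fraction)
    stratum = np.where(stratum_latent > cut, "urban", "rural")

    hh_ids = np.arange(1, n + 1)
    rows = {
        "household_id": np.repeat(hh_ids, T),
        "wave_id": np.tile(config.wave_ids, n),
        "year": np.tile(config.wave_years, n),
        "participation": np.ones(n * T, dtype=bool),
    }
    for name, mat in columns.items():
        rows[name] = mat.reshape(-1)
    rows["schooling"] = np.repeat(schooling, T)
    rows["haz_24m"] = np.repeat(np.round(haz, 3), T)
    rows["bmi_adult"] = np.repeat(np.round(bmi, 2), T)
    rows["stratum"] = np.repeat(stratum, T)
    df = pd.DataFrame(rows)

    truth = LatentTruth(
        wealth=pd.DataFrame({
            "household_id": np.repeat(hh_ids, T),
            "wave_id": np.tile(config.wave_ids, n),
            "w": w.reshape(-1),
        }),
        households=pd.DataFrame({
            "household_id": hh_ids,
            "alpha": alpha,
            "beta": beta,
            "schooling": schooling,
            "stratum": stratum,
        }),
    )
    panel = PanelDataset(
        data=df,
        asset_columns=config.asset_names,
        extra_columns=["schooling", "haz_24m", "bmi_adult", "stratum"],
    )
    return panel, truth


def apply_missingness(
    panel: PanelDataset, config: SyntheticConfig,
    truth: LatentTruth | None = None,
) -> PanelDataset:
    """Impose wave non-participation and planned item non-collection.

    From wave 2 on, each household drops out of a wave with probability
    ``dropout_probability`` (MCAR), or with a wealth-dependent probability
    logit(p) + mar_coefficient * w_ht (MAR; needs ``truth``).  With monotone
    attrition, dropout is absorbing; otherwise households may re-enter.
    Dropped household-waves have participation False and all assets missing.
    ``missing_asset_plan`` (asset, wave) pairs are blanked for everyone.
    """
    for name, wave in config.missing_asset_plan:
        if name not in panel.asset_columns:
            raise ValueError(f"missing_asset_plan references unknown asset {name!r}")
        if wave not in config.wave_ids:
            raise ValueError(f"missing_asset_plan references unknown wave {wave!r}")
    if config.attrition_mechanism == "MAR" and truth is None:
        raise ValueError("MAR attrition requires the latent truth")

    out = panel.copy()
    df = out.data
    rng = _child_rngs(config.seed)["attrition"]
    p = config.dropout_probability
    waves = config.wave_ids

    df = df.sort_values(["household_id", "wave_id"]).reset_index(drop=True)
    n = df["household_id"].nunique()
    part = np.ones((n, len(waves)), dtype=bool)
    if p > 0 and len(waves) > 1:
        if config.attrition_mechanism == "MAR":
            w_mat = (truth.wealth.sort_values(["household_id", "wave_id"])
                     ["w"].to_numpy().reshape(n, len(waves)))
            logit = np.log(p / (1 - p)) if 0 < p < 1 else None
        for ti in range(1, len(waves)):
            if config.attrition_mechanism == "MAR" and 0 < p < 1:
                prob = 1 / (1 + np.exp(-(logit + config.mar_coefficient
                                         * w_mat[:, ti])))
            else:
                prob = np.full(n, p)
            drop = rng.random(n) < prob
            part[:, ti] = ~drop
        if config.monotone_attrition:
            part = np.logical_and.accumulate(part, axis=1)

    df["participation"] = part.reshape(-1)
    absent = ~df["participation"].to_numpy()
    if absent.any():
        for name in out.asset_columns + ["haz_24m", "bmi_adult"]:
            if name in df.columns:
                df.loc[absent, name] = np.nan
    for name, wave in config.missing_asset_plan:
        df.loc[df["wave_id"] == wave, name] = np.nan
    out.data = df
    return out
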