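"""Panel/config IO and end-to-end pipeline orchestration.

CSV panels are long-format with one row per (household, wave); missing
values are empty fields ("NA" is also accepted).  The pipeline sequences
simulate/load -> asset selection -> imputation -> harmonized fit -> scoring
-> validation -> sensitivity and writes every table as plain text, plus a
human-readable summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonize, sensitivity, synthetic, validation
from .datatypes import AssetDictionary, ID_COLUMNS, PanelDataset

logger = logging.getLogger("wealthbridge.io")

_NA_VALUES = ["", "NA"]


@dataclass
class RunConfig:
    """Switches for a full pipeline run."""

    panel_path: str | None = None
    dictionary_path: str | None = None
    out_dir: str = "wealthbridge_out"
    anchor: str | None = None
    weighted: bool = False
    continuous_handling: str = "polyserial"  # or "quintile"
    nzv_threshold: float = validation.NZV_THRESHOLD
    min_wave_n: int = validation.MIN_WAVE_N
    sensitivity_modes: tuple = ("asset", "wave")
    sensitivity_methods: tuple = sensitivity.ALTERNATE_METHODS
    run_validation: bool = True
    run_sensitivity: bool = True
    seed: int = 0
    synthetic_config: synthetic.SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if not 0.5 <= self.nzv_threshold <= 1.0:
            raise ValueError("nzv_threshold must lie in [0.5, 1]")
        if self.min_wave_n < 3:
            raise ValueError("min_wave_n must be >= 3")


def read_panel(path, dictionary: AssetDictionary,
               extra_columns=None) -> PanelDataset:
    """Read and validate a long-format panel CSV against the dictionary."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV lacks required columns {missing}")
    dup = df.duplicated(subset=["household_id", "wave_id"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (household_id, wave_id) = "
            f"({row['household_id']!r}, {row['wave_id']!r})")
    df["participation"] = df["participation"].map(
        {True: True, False: False, "True": True, "False": False,
         1: True, 0: False, "1": True, "0": False})
    if df["participation"].isna().any():
        raise ValueError("participation column must be boolean")
    asset_columns = [a.name for a in dictionary if a.name in df.columns]
    unknown_assets = [a.name for a in dictionary if a.name not in df.columns]
    if unknown_assets:
        logger.info("dictionary assets absent from CSV: %s", unknown_assets)
    for name in asset_columns:
        try:
            dictionary.encode(df[name], name)  # validation pass
        except ValueError as exc:
            raise ValueError(f"column {name!r}: {exc}") from exc
    if extra_columns is None:
        extra_columns = [c for c in df.columns
                         if c not in asset_columns and c not in ID_COLUMNS]
    return PanelDataset(
        data=df, asset_columns=asset_columns, extra_columns=list(extra_columns))


@dataclass
class PipelineResult:
    panel: PanelDataset
    imputed: PanelDataset
    dictionary: AssetDictionary
    model: harmonize.IndexModel
    scores: harmonize.WealthScore
    wave_summary: pd.DataFrame
    validation_report: validation.ValidationReport | None = None
    sensitivity_report: sensitivity.SensitivityReport | None = None
    log_records: list = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write its report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records: list[str] = []
    handler = _ListHandler(records)
    root = logging.getLogger("wealthbridge")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if config.panel_path is not None:
            if config.dictionary_path is None:
                raise ValueError("a panel CSV requires a dictionary JSON")
            dictionary = AssetDictionary.from_json(config.dictionary_path)
            panel = read_panel(config.panel_path, dictionary)
            truth = None
        else:
            sim = config.synthetic_config or synthetic.SyntheticConfig(
                seed=config.seed)
            full, truth = synthetic.generate_panel(sim)
            panel = synthetic.apply_missingness(full, sim, truth)
            dictionary = sim.asset_dictionary()
            panel.to_csv(out / "panel.csv")
            dictionary.to_json(out / "dictionary.json")
            truth.to_csv(out / "latent_wealth.csv", out / "latent_households.csv")

        waves = panel.waves
        usable_waves = [w for w in waves
                        if len(panel.participants(w)) >= config.min_wave_n]
        if not usable_waves:
            raise ValueError(
                f"no wave has >= {config.min_wave_n} participants; cannot fit")

        common = harmonize.select_common_assets(dictionary, waves)
        imputed = harmonize.impute_missing(panel, common, dictionary)
        fit_weights = None
        if config.weighted:
            rows = imputed.participants()
            counts = rows["wave_id"].value_counts()
            fit_weights = rows["wave_id"].map(
                lambda w: 1.0 / counts[w]).to_numpy()
        model = harmonize.fit_harmonized_index(
            imputed, dictionary, assets=common, weights=fit_weights,
            anchor=config.anchor,
            continuous_handling=config.continuous_handling)
        scores = harmonize.score(model, imputed)
        wave_summary = harmonize.summarize_by_wave(scores)

        model.to_json(out / "index_model.json")
        with open(out / "correlation_sidecar.json", "w") as fh:
            json.dump(model.correlation.sidecar_json(), fh, indent=2)
        model.correlation.to_csv(out / "correlation_matrix.csv")
        model.loadings_table().to_csv(out / "loadings.csv", index=False)
        scores.to_csv(out / "scores.csv")
        wave_summary.to_csv(out / "wave_summary.csv", index=False)

        vreport = None
        if config.run_validation:
            strata = None
            if "stratum" in panel.data.columns:
                observed = panel.participants()["stratum"].dropna().unique()
                strata = sorted(observed) if len(observed) > 1 else None
            vreport = validation.validate_harmonized(
                imputed, dictionary, model, scores, strata=strata,
                anchor=config.anchor,
                continuous_handling=config.continuous_handling)
            vreport.to_json(out / "validation_report.json")
            vreport.same_asset.to_csv(out / "rho_same_assets.csv", index=False)
            vreport.all_asset.to_csv(out / "rho_all_assets.csv", index=False)
            vreport.congruence.to_csv(out / "tucker_congruence.csv", index=False)
            vreport.construct.to_csv(out / "construct_validity.csv", index=False)
            for wave, hist in vreport.histograms.items():
                hist.to_csv(out / f"histogram_wave_{wave}.csv", index=False)

        sreport = None
        if config.run_sensitivity:
            sreport = sensitivity.run_sensitivity(
                imputed, dictionary, scores, assets=model.assets,
                anchor=config.anchor, modes=config.sensitivity_modes,
                methods=config.sensitivity_methods, weighted=True,
                continuous_handling=config.continuous_handling)
            sreport.to_json(out / "sensitivity_report.json")

        _write_summary(out / "summary.txt", model, wave_summary, vreport,
                       sreport, records)
        n_imputed = int(imputed.imputation_flags.to_numpy().sum())
        logger.info("pipeline complete: %d imputed cells", n_imputed)
        return PipelineResult(
            panel=panel, imputed=imputed, dictionary=dictionary, model=model,
            scores=scores, wave_summary=wave_summary,
            validation_report=vreport, sensitivity_report=sreport,
            log_records=records)
    finally:
        root.removeHandler(handler)


class _ListHandler(logging.Handler):
    def __init__(self, sink: list):
        super().__init__(level=logging.INFO)
        self._sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self._sink.append(self.format(record))


def _write_summary(path, model, wave_summary, vreport, sreport, records):
    lines = [
        "Temporally-harmonized wealth index",
        "=" * 40,
        f"assets: {len(model.assets)} ({', '.join(model.assets)})",
        f"variance explained by first component: "
        f"{model.variance_explained_pct:.1f}%",
        f"anchor asset: {model.anchor_asset} (sign {model.anchor_sign:+.0f})",
        "",
        "Per-wave summary (mean +/- SD, median [IQR]):",
    ]
    for _, row in wave_summary.iterrows():
        lines.append(
            f"  wave {row['wave_id']} ({row['year']}): "
            f"{row['mean']:+.2f} +/- {row['sd']:.2f}, "
            f"{row['median']:+.2f} [{row['iqr_low']:+.2f}, "
            f"{row['iqr_high']:+.2f}]  (n={int(row['n'])})")
    if vreport is not None and len(vreport.same_asset):
        lines += ["", "Validation (Spearman vs cross-sectional, same assets):"]
        for _, row in vreport.same_asset.iterrows():
            lines.append(f"  wave {row['wave_id']}: rho = {row['rho']:.3f}")
    if sreport is not None:
        lines += ["", "Sensitivity minima:"]
        for k, v in sreport.minima().items():
            if np.isfinite(v):
                lines.append(f"  {k}: {v:.3f}")
    if records:
        lines += ["", f"Structured log ({len(records)} entries):"]
        lines += [f"  {r}" for r in records]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
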