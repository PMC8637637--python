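import numpy as np
import pandas as pd
import pytest

import wealthbridge as wb


@pytest.fixture(scope="session")
def bundle500():
    """A mid-sized synthetic cohort with its fitted harmonized index.

    500 households keep the session-wide fixtures fast while leaving enough
    signal for the recovery-style unit checks; the acceptance suite refits
    at the full default size.
    """
    cfg = wb.SyntheticConfig(n_households=500, seed=11)
    full, truth = wb.generate_panel(cfg)
    panel = wb.apply_missingness(full, cfg, truth)
    dictionary = cfg.asset_dictionary()
    common = wb.select_common_assets(dictionary, panel.waves)
    imputed = wb.impute_missing(panel, common, dictionary)
    model = wb.fit_harmonized_index(imputed, dictionary, assets=common)
    scores = wb.score(model, imputed)
    return {
        "config": cfg, "truth": truth, "panel": panel,
        "dictionary": dictionary, "common": common, "imputed": imputed,
        "model": model, "scores": scores,
    }


@pytest.fixture()
def toy_dictionary():
    return wb.AssetDictionary([
        wb.Asset("tv", "binary", (1, 2, 3), (0, 1), "positive"),
        wb.Asset("radio", "binary", (1, 2, 3), (0, 1), "negative"),
        wb.Asset("roof", "ordinal", (1, 2, 3), ("Low", "Medium", "High"),
                 "positive"),
    ])


def make_toy_panel(rows, asset_columns=("tv", "radio", "roof")):
    """Build a PanelDataset from (household, wave, year, part, *assets) rows."""
    cols = ["household_id", "wave_id", "year", "participation",
            *asset_columns]
    df = pd.DataFrame(rows, columns=cols)
    return wb.PanelDataset(data=df, asset_columns=list(asset_columns))


@pytest.fixture()
def toy_panel():
    years = {1: 2000, 2: 2005, 3: 2010}
    rows = []
    for h in (1, 2, 3):
        for w in (1, 2, 3):
            rows.append([h, w, years[w], True, (h + w) % 2, h % 2,
                         ["Low", "Medium", "High"][(h + w) % 3]])
    return make_toy_panel(rows)


def panel_from_codes(codes: pd.DataFrame, dictionary, wave_id=1, year=2000):
    """Wrap a numeric code frame as a single-wave PanelDataset."""
    df = codes.reset_index(drop=True).copy()
    decoded = {}
    for name in df.columns:
        asset = dictionary[name]
        if asset.categories is not None:
            cats = np.asarray(asset.categories, dtype=object)
            decoded[name] = cats[df[name].astype(int).to_numpy()]
        else:
            decoded[name] = df[name].to_numpy()
    out = pd.DataFrame(decoded)
    out.insert(0, "household_id", np.arange(1, len(df) + 1))
    out.insert(1, "wave_id", wave_id)
    out.insert(2, "year", year)
    out.insert(3, "participation", True)
    return wb.PanelDataset(data=out, asset_columns=list(df.columns))
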