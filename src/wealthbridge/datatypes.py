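"""Core data containers: asset metadata and long-format household panels.

An :class:`AssetDictionary` declares, for every asset indicator, its
measurement type (binary ownership, ordered housing quality, count,
continuous), the ordered category labels with the convention that a higher
category means a wealthier household, and the set of study waves at which the
indicator was collected.  A :class:`PanelDataset` holds the long-format
household-by-wave observations together with participation flags and any
external validation columns (schooling, anthropometry, urban/rural stratum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MEASUREMENT_TYPES = ("binary", "ordinal", "count", "continuous")

#: reserved (non-asset) panel columns
ID_COLUMNS = ("household_id", "wave_id", "year", "participation")
EXTERNAL_COLUMNS = ("schooling", "maternal_schooling", "attained_schooling",
                    "haz_24m", "bmi_adult", "stratum")


class DegenerateVariableError(ValueError):
    """Raised when a variable has fewer than two observed categories."""


@dataclass
class Asset:
    """Metadata for a single asset indicator."""

    name: str
    measurement_type: str
    waves_collected: tuple
    categories: tuple | None = None  # ordered low -> high, binary/ordinal only
    orientation_hint: str = "unknown"  # positive | negative | unknown

    def __post_init__(self) -> None:
        if self.measurement_type not in MEASUREMENT_TYPES:
            raise ValueError(
                f"asset {self.name!r}: unknown measurement type "
                f"{self.measurement_type!r}"
            )
        if not self.waves_collected:
            raise ValueError(f"asset {self.name!r}: empty waves_collected")
        self.waves_collected = tuple(self.waves_collected)
        if self.categories is not None:
            self.categories = tuple(self.categories)
            if len(self.categories) < 2:
                raise ValueError(
                    f"asset {self.name!r}: needs >= 2 ordered categories"
                )
        if self.measurement_type == "ordinal" and self.categories is None:
            raise ValueError(
                f"asset {self.name!r}: ordinal asset requires categories"
            )
        if self.orientation_hint not in ("positive", "negative", "unknown"):
            raise ValueError(
                f"asset {self.name!r}: bad orientation hint "
                f"{self.orientation_hint!r}"
            )


class AssetDictionary:
    """Ordered collection of :class:`Asset` entries with unique names."""

    def __init__(self, assets: Iterable[Asset]):
        assets = list(assets)
        names = [a.name for a in assets]
        if len(set(names)) != len(names):
            raise ValueError("asset names must be unique")
        self._assets = {a.name: a for a in assets}

    def __getitem__(self, name: str) -> Asset:
        return self._assets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._assets

    def __iter__(self):
        return iter(self._assets.values())

    def __len__(self) -> int:
        return len(self._assets)

    @property
    def names(self) -> list[str]:
        return list(self._assets)

    def subset(self, names: Sequence[str]) -> "AssetDictionary":
        return AssetDictionary([self._assets[n] for n in names])

    # -- encoding ---------------------------------------------------------

    def encode(self, values: pd.Series, name: str) -> pd.Series:
        """Map raw asset values to numeric codes.

        Binary and ordinal labels become their 0-based rank in the ordered
        category list; counts and continuous values pass through as floats.
        Missing values stay missing.  Unknown labels raise ``ValueError``.
        """
        asset = self._assets[name]
        if asset.measurement_type in ("count", "continuous"):
            return pd.to_numeric(values, errors="raise").astype(float)
        cats = asset.categories
        if cats is None:  # binary declared without labels: expect 0/1
            coded = pd.to_numeric(values, errors="raise").astype(float)
            bad = coded.dropna()[~coded.dropna().isin([0.0, 1.0])]
            if len(bad):
                raise ValueError(
                    f"asset {name!r}: non-binary value {bad.iloc[0]!r}"
                )
            return coded
        mapping = {c: float(i) for i, c in enumerate(cats)}
        # tolerate values already given as integer codes
        for i in range(len(cats)):
            mapping.setdefault(i, float(i))
            mapping.setdefault(float(i), float(i))
            mapping.setdefault(str(i), float(i))
        out = values.map(mapping)
        unknown = values.notna() & out.isna()
        if unknown.any():
            bad = values[unknown].iloc[0]
            raise ValueError(
                f"asset {name!r}: category {bad!r} not in dictionary "
                f"{list(cats)}"
            )
        return out.astype(float)

    # -- (de)serialisation ------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = [
            {
                "name": a.name,
                "measurement_type": a.measurement_type,
                "categories": list(a.categories) if a.categories else None,
                "waves_collected": list(a.waves_collected),
                "orientation_hint": a.orientation_hint,
            }
            for a in self
        ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AssetDictionary":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("["):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls(
            Asset(
                name=e["name"],
                measurement_type=e["measurement_type"],
                waves_collected=tuple(e["waves_collected"]),
                categories=tuple(e["categories"]) if e.get("categories") else None,
                orientation_hint=e.get("orientation_hint", "unknown"),
            )
            for e in payload
        )


@dataclass
class PanelDataset:
    """Long-format household x wave panel.

    ``data`` has one row per (household_id, wave_id) with columns
    household_id, wave_id, year, participation, one column per asset, and
    optional external columns.  Non-participant rows carry all-missing asset
    values.
    """

    data: pd.DataFrame
    asset_columns: list[str]
    extra_columns: list[str] = field(default_factory=list)
    imputation_flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing required columns {missing}")
        dup = self.data.duplicated(subset=["household_id", "wave_id"])
        if dup.any():
            key = self.data.loc[dup.idxmax(), ["household_id", "wave_id"]]
            raise ValueError(
                "duplicate (household_id, wave_id) key: "
                f"({key['household_id']!r}, {key['wave_id']!r})"
            )

    @property
    def waves(self) -> list:
        seen = self.data[["wave_id", "year"]].drop_duplicates()
        return list(seen.sort_values("year")["wave_id"])

    @property
    def wave_years(self) -> dict:
        seen = self.data[["wave_id", "year"]].drop_duplicates()
        return dict(zip(seen["wave_id"], seen["year"]))

    def participants(self, wave=None) -> pd.DataFrame:
        df = self.data[self.data["participation"].astype(bool)]
        if wave is not None:
            df = df[df["wave_id"] == wave]
        return df

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            data=self.data.copy(),
            asset_columns=list(self.asset_columns),
            extra_columns=list(self.extra_columns),
            imputation_flags=None
            if self.imputation_flags is None
            else self.imputation_flags.copy(),
        )

    # -- IO ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        cols = list(ID_COLUMNS) + self.asset_columns + self.extra_columns
        self.data[cols].to_csv(path, index=False, na_rep="")

    def encoded(self, dictionary: AssetDictionary,
                assets: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric codes for the given assets over participant rows."""
        assets = list(assets) if assets is not None else list(self.asset_columns)
        rows = self.participants()
        out = pd.DataFrame(index=rows.index)
        for name in assets:
            out[name] = dictionary.encode(rows[name], name)
        return out
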