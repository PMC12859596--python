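"""In-memory containers for stratified count panels and covariates.

The observational unit is the (area, year, age-band, sex) stratum; every
area-year must carry a complete stratum grid so that indirect
standardisation and the space-time index grid stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StratifiedPanel",
    "CovariateMatrix",
    "ExpectedCounts",
    "DEFAULT_AGE_BANDS",
    "DEFAULT_SEXES",
]

DEFAULT_AGE_BANDS = [
    "15-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85plus",
]
DEFAULT_SEXES = ["female", "male"]

PANEL_COLUMNS = ["area_id", "year", "age_band", "sex", "population", "deaths"]


@dataclass
class StratifiedPanel:
    """Counts and person-years per (area, year, age-band, sex).

    Wraps a long-format DataFrame with columns
    ``area_id, year, age_band, sex, population, deaths`` and validates the
    structural invariants on construction: complete stratum grid, integer
    non-negative deaths, and deaths <= population elementwise.
    """

    data: pd.DataFrame
    age_bands: list[str] = field(default=None)  # type: ignore[assignment]
    sexes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"panel is missing columns {missing_cols}")
        df = df[PANEL_COLUMNS].copy()
        df["area_id"] = df["area_id"].astype(str)
        df["year"] = df["year"].astype(int)
        if self.age_bands is None:
            self.age_bands = sorted(df["age_band"].unique().tolist())
        if self.sexes is None:
            self.sexes = sorted(df["sex"].unique().tolist())

        deaths = df["deaths"].to_numpy()
        if not np.allclose(deaths, np.round(deaths)):
            raise ValueError("deaths must be integers")
        df["deaths"] = np.round(deaths).astype(np.int64)
        if (df["deaths"] < 0).any():
            raise ValueError("deaths must be non-negative")
        if (df["population"] < 0).any():
            raise ValueError("populations must be non-negative")
        bad = df[df["deaths"] > df["population"]]
        if len(bad):
            key = bad.iloc[0]
            raise ValueError(
                "deaths exceed population at "
                f"({key.area_id}, {key.year}, {key.age_band}, {key.sex})"
            )

        keys = ["area_id", "year", "age_band", "sex"]
        if df.duplicated(keys).any():
            dup = df[df.duplicated(keys)].iloc[0]
            raise ValueError(
                f"duplicate stratum row ({dup.area_id}, {dup.year}, "
                f"{dup.age_band}, {dup.sex})"
            )
        full = pd.MultiIndex.from_product(
            [sorted(df["area_id"].unique()), sorted(df["year"].unique()),
             self.age_bands, self.sexes],
            names=keys,
        )
        have = pd.MultiIndex.from_frame(df[keys])
        missing = full.difference(have)
        if len(missing):
            raise ValueError(f"incomplete stratum grid: missing {missing[0]}")

        self.data = df.sort_values(keys, kind="stable").reset_index(drop=True)

    # -- index helpers -------------------------------------------------
    @property
    def area_ids(self) -> list[str]:
        return sorted(self.data["area_id"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def total_deaths(self) -> int:
        return int(self.data["deaths"].sum())

    def totals(self) -> np.ndarray:
        """Total deaths per (area, year) as an ``(n_areas, n_years)`` array."""
        tab = (
            self.data.groupby(["area_id", "year"], sort=True)["deaths"]
            .sum()
            .unstack("year")
        )
        return tab.loc[self.area_ids, self.years].to_numpy()


@dataclass
class CovariateMatrix:
    """Area-level covariates: ``values`` is ``(n_areas, K)``, one row per area.

    Columns are expected to be standardised (mean 0, sd 1); use
    :meth:`standardize` to enforce it and :meth:`is_standardized` to check.
    """

    values: np.ndarray
    names: list[str]
    area_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariate values must be 2-d (areas x K)")
        if self.values.shape[1] != len(self.names):
            raise ValueError("number of names must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariates contain non-finite values")
        if self.area_ids is not None and len(self.area_ids) != self.values.shape[0]:
            raise ValueError("area_ids length must match number of rows")

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def standardize(self) -> "CovariateMatrix":
        """Return a copy with every column centred and scaled to unit sd."""
        sd = self.values.std(axis=0)
        if np.any(sd == 0):
            bad = self.names[int(np.argmin(sd))]
            raise ValueError(f"covariate {bad!r} is constant and cannot be standardised")
        vals = (self.values - self.values.mean(axis=0)) / sd
        return CovariateMatrix(vals, list(self.names), self.area_ids)

    def is_standardized(self, tol: float = 1e-6) -> bool:
        return bool(
            np.all(np.abs(self.values.mean(axis=0)) < tol)
            and np.all(np.abs(self.values.std(axis=0) - 1) < tol)
        )


@dataclass
class ExpectedCounts:
    """Indirectly standardised expected counts E per (area, year)."""

    values: np.ndarray
    area_ids: list[str]
    years: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.area_ids), len(self.years)):
            raise ValueError("expected counts shape mismatch with area/year labels")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("expected counts must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.area_ids):
            for t, y in enumerate(self.years):
                rows.append((a, y, self.values[i, t]))
        return pd.DataFrame(rows, columns=["area_id", "year", "expected"])
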