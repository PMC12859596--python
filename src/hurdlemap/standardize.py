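"""Age-sex indirect standardisation.

Reference rates are pooled over the entire panel (all areas and years),
so the standardisation is internal: the sum of the expected counts
equals the sum of the observed deaths exactly.  The expected counts act
as the offset of the count component of the hurdle model, hence they
must be strictly positive wherever the area-year has any population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpectedCounts, StratifiedPanel

__all__ = ["ReferenceRates", "compute_reference_rates", "compute_expected_counts"]


@dataclass
class ReferenceRates:
    """Deaths per person-year for each (age-band, sex) stratum."""

    rates: dict[tuple[str, str], float]

    def __getitem__(self, stratum: tuple[str, str]) -> float:
        return self.rates[stratum]

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, s, r) for (a, s), r in sorted(self.rates.items())]
        return pd.DataFrame(rows, columns=["age_band", "sex", "rate"])


def compute_reference_rates(panel: StratifiedPanel) -> ReferenceRates:
    """Pooled stratum-specific rates: total deaths / total person-years.

    Pools over all areas and years, i.e. uses the whole study region and
    period as the reference population.  Raises if any stratum has zero
    pooled population (its rate would be undefined).
    """
    grouped = panel.data.groupby(["age_band", "sex"], sort=True)[["deaths", "population"]].sum()
    rates: dict[tuple[str, str], float] = {}
    for (age_band, sex), row in grouped.iterrows():
        if row["population"] <= 0:
            raise ValueError(
                f"stratum ({age_band}, {sex}) has zero pooled population; "
                "reference rate undefined"
            )
        rates[(age_band, sex)] = float(row["deaths"] / row["population"])
    return ReferenceRates(rates)


def compute_expected_counts(
    panel: StratifiedPanel, rates: ReferenceRates
) -> ExpectedCounts:
    """E(i, t) = sum over strata of population(i, t, a, s) * rate(a, s)."""
    df = panel.data.copy()
    strata = set(zip(df["age_band"], df["sex"]))
    missing = strata - set(rates.rates)
    if missing:
        raise ValueError(f"reference rates missing for stratum {sorted(missing)[0]}")
    rate_col = np.array([rates.rates[k] for k in zip(df["age_band"], df["sex"])])
    df["expected"] = df["population"].to_numpy() * rate_col
    tab = df.groupby(["area_id", "year"], sort=True)["expected"].sum().unstack("year")
    area_ids, years = panel.area_ids, panel.years
    return ExpectedCounts(tab.loc[area_ids, years].to_numpy(), area_ids, years)
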