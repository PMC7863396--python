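"""LMS growth-reference z-scores for child anthropometrics.

Growth references publish, per sex and age, a Box-Cox skewness power L, a
median M, and a coefficient of variation S. A measurement x maps to

    z = ((x / M)^L - 1) / (L * S)        for |L| > 1e-8
    z = ln(x / M) / S                    as the L -> 0 limit,

which is invertible, strictly increasing in x, and continuous across the
branch switch. Reference tables are user-supplied CSV (the actual Finnish
and WHO tables are not redistributed here); a synthetic reference with
plausible preschool-age curves ships for tests and simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, OutOfRangeError

_L_SWITCH = 1e-8

#: age (years) at and below which the younger of two MUAC tables applies
MUAC_TABLE_BOUNDARY = 5.0


@dataclass
class LMSTable:
    """Per-sex, per-age (L, M, S) rows for one measure."""

    data: pd.DataFrame  # columns: sex, age_years, L, M, S
    measure: str = ""
    units: str = ""
    _by_sex: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"sex", "age_years", "L", "M", "S"}
        missing = required - set(self.data.columns)
        if missing:
            raise InputError(f"LMS table missing columns {sorted(missing)}")
        for sex, sub in self.data.groupby("sex"):
            ages = sub["age_years"].to_numpy(dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise InputError(
                    f"LMS ages for sex {sex!r} must be strictly increasing"
                )
            if (sub["M"] <= 0).any() or (sub["S"] <= 0).any():
                raise InputError("LMS table requires M > 0 and S > 0")
            self._by_sex[sex] = sub.reset_index(drop=True)

    @property
    def sexes(self) -> list:
        return sorted(self._by_sex)

    def span(self, sex) -> tuple[float, float]:
        ages = self._rows(sex)["age_years"]
        return float(ages.iloc[0]), float(ages.iloc[-1])

    def _rows(self, sex) -> pd.DataFrame:
        try:
            return self._by_sex[sex]
        except KeyError:
            raise InputError(
                f"unknown sex code {sex!r}; table covers {self.sexes}"
            ) from None

    @classmethod
    def from_csv(cls, path, measure: str | None = None) -> "LMSTable":
        """Load from CSV with columns measure,sex,age_years,L,M,S."""
        df = pd.read_csv(path, comment="#")
        if measure is not None:
            df = df[df["measure"] == measure]
            if df.empty:
                raise InputError(f"no rows for measure {measure!r} in {path}")
        name = measure or (df["measure"].iloc[0] if "measure" in df else "")
        return cls(df.drop(columns=["measure"], errors="ignore"), measure=name)


def interpolate_lms(table: LMSTable, sex, age: float) -> tuple[float, float, float]:
    """(L, M, S) at an arbitrary age by linear interpolation in age.

    An age on the grid returns that row exactly; an age outside the covered
    span raises rather than extrapolating.
    """
    rows = table._rows(sex)
    lo, hi = table.span(sex)
    if not lo <= age <= hi:
        raise OutOfRangeError(
            f"age {age} outside LMS span [{lo}, {hi}] for sex {sex!r}"
        )
    ages = rows["age_years"].to_numpy(dtype=float)
    return tuple(
        float(np.interp(age, ages, rows[c].to_numpy(dtype=float)))
        for c in ("L", "M", "S")
    )


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    if x <= 0 or M <= 0:
        raise InputError(f"lms_zscore requires x > 0 and M > 0 (got x={x}, M={M})")
    if abs(L) > _L_SWITCH:
        # expm1 keeps precision when L*ln(x/M) is tiny (L near the switch)
        return float(np.expm1(L * np.log(x / M)) / (L * S))
    return float(np.log(x / M) / S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement at a given z — exact inverse of :func:`lms_zscore`."""
    if abs(L) > _L_SWITCH:
        return float(M * np.exp(np.log1p(L * S * z) / L))
    return float(M * np.exp(S * z))


def zscore(table: LMSTable, sex, age: float, x: float) -> float:
    """Convenience: interpolate the reference then transform x."""
    return lms_zscore(x, *interpolate_lms(table, sex, age))


def muac_zscore(cohort, muac_table, older_table: LMSTable | None = None) -> pd.Series:
    """Mid-upper arm circumference z per participant.

    The WHO reference splits at five years; when two tables are supplied the
    participant's age picks the table, with the boundary age itself belonging
    to the younger table.
    """
    out = {}
    for row in cohort.participants.itertuples():
        table = muac_table
        if older_table is not None and row.age_years > MUAC_TABLE_BOUNDARY:
            table = older_table
        out[row.id] = zscore(table, row.sex, row.age_years, row.muac_cm)
    return pd.Series(out, name="muac_z")


def zscore_cohort(cohort, tables: dict[str, LMSTable]) -> pd.DataFrame:
    """Height, BMI, and MUAC z-scores for every participant.

    BMI is weight / height^2 in kg/m^2, computed before z-scoring. ``tables``
    maps measure name ("height", "bmi", "muac", optionally "muac_over5") to
    its LMS table; absent measures are skipped.
    """
    parts = cohort.participants
    out = pd.DataFrame(index=parts["id"].to_numpy())
    out.index.name = "id"
    if "height" in tables:
        out["height_z"] = [
            zscore(tables["height"], r.sex, r.age_years, r.height_cm)
            for r in parts.itertuples()
        ]
    if "bmi" in tables:
        bmi = parts["weight_kg"] / (parts["height_cm"] / 100.0) ** 2
        out["bmi_z"] = [
            zscore(tables["bmi"], r.sex, r.age_years, b)
            for r, b in zip(parts.itertuples(), bmi)
        ]
    if "muac" in tables:
        out["muac_z"] = muac_zscore(
            cohort, tables["muac"], tables.get("muac_over5")
        ).reindex(out.index)
    return out


def synthetic_growth_reference(measure: str, age_grid=None) -> LMSTable:
    """Synthetic LMS reference for tests and the cohort simulator.

    Smooth, physiologically plausible preschool curves (ages 1-8 y) for
    height (cm), BMI (kg/m^2), and MUAC (cm). These are NOT the Finnish or
    WHO reference values — they exist only so the full z-scoring machinery
    can run without redistributing licensed tables.
    """
    if age_grid is None:
        age_grid = np.arange(1.0, 8.01, 0.5)
    rows = []
    for sex, shift in (("F", -0.6), ("M", 0.0)):
        for age in age_grid:
            if measure == "height":
                L, M, S = 1.0, 68.0 + 8.5 * age - 0.25 * age**2 + shift, 0.040
            elif measure == "bmi":
                L, M, S = -1.5, 16.6 - 0.28 * age + 0.022 * age**2 + 0.1 * shift, 0.080
            elif measure == "muac":
                L, M, S = 0.5, 14.8 + 0.28 * age + 0.05 * shift, 0.070
            else:
                raise InputError(f"unknown synthetic measure {measure!r}")
            rows.append((sex, float(age), L, float(M), S))
    df = pd.DataFrame(rows, columns=["sex", "age_years", "L", "M", "S"])
    units = {"height": "cm", "bmi": "kg/m^2", "muac": "cm"}[measure]
    return LMSTable(df, measure=measure, units=units)
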