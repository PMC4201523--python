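"""Age- and sex-specific remaining life expectancy tables.

A life table here is a long-format table of (age, sex, remaining life
expectancy in years).  Lookups return the exact row when present,
interpolate linearly between bracketing ages, and clamp to the oldest
row above the table maximum (extrapolating a downward trend past the
table would eventually produce negative expectancies).  Ages below the
table minimum are an error: the table does not describe them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LifeTableError, SchemaError

__all__ = ["LifeTable", "read_life_table", "LIFE_TABLE_COLUMNS"]

LIFE_TABLE_COLUMNS = ["age", "sex", "life_expectancy_years"]
VALID_SEXES = ("male", "female")


@dataclass
class LifeTable:
    """Validated remaining-life-expectancy lookup.

    ``data`` holds one row per (age, sex) with columns
    ``age, sex, life_expectancy_years``; within each sex the expectancy
    is strictly positive and non-increasing in age.
    """

    data: pd.DataFrame
    provenance: str = ""
    _by_sex: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in LIFE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"life table missing columns: {missing}")
        if df.empty:
            raise LifeTableError("life table is empty")
        df = df.copy()
        df["age"] = df["age"].astype(float)
        df["life_expectancy_years"] = df["life_expectancy_years"].astype(float)
        bad_sex = set(df["sex"]) - set(VALID_SEXES)
        if bad_sex:
            raise LifeTableError(f"unknown sex values in life table: {sorted(bad_sex)}")
        if df.duplicated(subset=["age", "sex"]).any():
            dup = df[df.duplicated(subset=["age", "sex"], keep=False)]
            raise LifeTableError(
                f"duplicate (age, sex) rows in life table: {dup[['age', 'sex']].values.tolist()}"
            )
        if (df["life_expectancy_years"] <= 0).any():
            raise LifeTableError("life expectancy values must be strictly positive")
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age")
            if len(grp) < 2:
                raise LifeTableError(f"need at least two ages per sex, sex={sex!r} has {len(grp)}")
            ex = grp["life_expectancy_years"].to_numpy()
            if (np.diff(ex) > 0).any():
                raise LifeTableError(
                    f"life expectancy must be non-increasing in age for sex={sex!r}"
                )
            self._by_sex[sex] = (grp["age"].to_numpy(), ex)
        self.data = df.sort_values(["sex", "age"]).reset_index(drop=True)

    @property
    def age_bounds(self) -> tuple[float, float]:
        return float(self.data["age"].min()), float(self.data["age"].max())

    def sexes(self) -> list[str]:
        return sorted(self._by_sex)

    def expectancy(self, age: float, sex: str) -> float:
        """Remaining life expectancy at ``age`` for ``sex``.

        Exact row if present; linear interpolation between bracketing
        ages; ages above the table maximum clamp to the oldest row.
        """
        if sex not in self._by_sex:
            raise LifeTableError(f"sex {sex!r} absent from life table")
        ages, ex = self._by_sex[sex]
        if age < ages[0]:
            raise LifeTableError(
                f"age {age} below life-table minimum {ages[0]} for sex={sex!r}"
            )
        # np.interp clamps on the right, which is the documented rule.
        return float(np.interp(age, ages, ex))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, columns=LIFE_TABLE_COLUMNS)


def read_life_table(path) -> LifeTable:
    """Read and validate a life-table CSV with header ``age,sex,life_expectancy_years``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise LifeTableError(f"life table file {path} is empty") from exc
    return LifeTable(df, provenance=str(path))
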