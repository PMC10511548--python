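"""Background mortality: life-table container, CSV I/O, and a parametric generator.

National period life tables are represented as annual death probabilities
``qx`` by single year of age and sex.  Where no national table is supplied,
a Gompertz generator provides a synthetic stand-in: the adult force of
mortality grows exponentially with age, ``mu(age) = a * exp(b * age)``, so
``qx = 1 - exp(-mu)``.  Male mortality is scaled by a constant hazard factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "LifeTable",
    "GompertzLifeTableSpec",
    "generate_life_table",
    "load_life_table",
    "save_life_table",
    "resolve_life_table",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by age (0-based single years) and sex.

    The last entry of each array is the terminal age, where ``qx = 1`` —
    every cohort member is absorbed there at the latest.
    """

    qx_female: np.ndarray
    qx_male: np.ndarray

    def __post_init__(self) -> None:
        for name, qx in (("qx_female", self.qx_female), ("qx_male", self.qx_male)):
            qx = np.asarray(qx, dtype=float)
            object.__setattr__(self, name, qx)
            if qx.ndim != 1 or qx.size < 2:
                raise ValidationError(f"{name}: need a 1-d array of at least 2 ages")
            if np.any((qx < 0) | (qx > 1)):
                raise ValidationError(f"{name}: qx must lie in [0, 1]")
            if qx[-1] != 1.0:
                raise ValidationError(f"{name}: terminal age must have qx = 1")
        if self.qx_female.size != self.qx_male.size:
            raise ValidationError("qx_female/qx_male: age ranges differ")

    @property
    def terminal_age(self) -> int:
        return self.qx_female.size - 1

    def qx(self, sex: str) -> np.ndarray:
        if sex not in ("f", "m"):
            raise ValidationError(f"sex: expected 'f' or 'm', got {sex!r}")
        return self.qx_female if sex == "f" else self.qx_male

    def __eq__(self, other: object) -> bool:  # array fields break dataclass eq
        if not isinstance(other, LifeTable):
            return NotImplemented
        return np.array_equal(self.qx_female, other.qx_female) and np.array_equal(
            self.qx_male, other.qx_male
        )


@dataclass(frozen=True)
class GompertzLifeTableSpec:
    """Parametric stand-in for a national life table.

    a:            baseline hazard per year at age 0 (female scale)
    b:            log-hazard slope per year of age
    terminal_age: age at which qx is forced to 1
    male_factor:  constant hazard multiplier for males
    """

    a: float
    b: float
    terminal_age: int = 110
    male_factor: float = 1.6

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValidationError(f"a: must be > 0, got {self.a}")
        if not self.b > 0:
            raise ValidationError(f"b: must be > 0, got {self.b}")
        if self.terminal_age < 1:
            raise ValidationError(f"terminal_age: must be >= 1, got {self.terminal_age}")
        if not self.male_factor > 0:
            raise ValidationError(f"male_factor: must be > 0, got {self.male_factor}")


def generate_life_table(spec: GompertzLifeTableSpec) -> LifeTable:
    """Deterministically expand a Gompertz spec into a full life table."""
    ages = np.arange(spec.terminal_age + 1)
    hazard = spec.a * np.exp(spec.b * ages)
    qx_f = 1.0 - np.exp(-hazard)
    qx_m = 1.0 - np.exp(-hazard * spec.male_factor)
    qx_f[-1] = 1.0
    qx_m[-1] = 1.0
    return LifeTable(qx_female=qx_f, qx_male=qx_m)


def load_life_table(path) -> LifeTable:
    """Read a delimited life table with header ``age,sex,qx`` (sex: f/m)."""
    df = pd.read_csv(path)
    missing = {"age", "sex", "qx"} - set(df.columns)
    if missing:
        raise ValidationError(f"life table {path}: missing columns {sorted(missing)}")
    cols = {}
    for sex in ("f", "m"):
        sub = df[df["sex"] == sex].sort_values("age")
        ages = sub["age"].to_numpy()
        if ages.size == 0 or ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise ValidationError(
                f"life table {path}: sex {sex!r} must cover contiguous ages from 0"
            )
        cols[sex] = sub["qx"].to_numpy(dtype=float)
    return LifeTable(qx_female=cols["f"], qx_male=cols["m"])


def save_life_table(table: LifeTable, path) -> None:
    rows = []
    for sex in ("f", "m"):
        qx = table.qx(sex)
        rows.append(
            pd.DataFrame({"age": np.arange(qx.size), "sex": sex, "qx": qx})
        )
    pd.concat(rows).to_csv(path, index=False)


def resolve_life_table(ref) -> LifeTable:
    """Accept a LifeTable, a Gompertz spec, or a CSV path."""
    if isinstance(ref, LifeTable):
        return ref
    if isinstance(ref, GompertzLifeTableSpec):
        return generate_life_table(ref)
    return load_life_table(ref)
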