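"""Shared data model and CSV I/O for bilateral measurement and covariate tables.

The pipeline works from two inputs:

* a long-format bilateral measurement table — one row per
  (individual, trait, side, replicate) with the measured value in mm;
* a covariate table — one row per individual, with a mix of quantitative
  and categorical early-life variables, declared by a
  :class:`CovariateSchema`.

All readers validate on load and raise :class:`SchemaError` /
:class:`ValidationError` with row-level detail, so malformed files fail
fast rather than propagating silently into the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MEASUREMENT_COLUMNS = ["individual_id", "sex", "trait_id", "side", "replicate", "value_mm"]
SEXES = ("F", "M")
SIDES = ("L", "R")

# sentinel strings accepted as missing covariate cells
NA_STRINGS = ("", "NA")


class SchemaError(ValueError):
    """The file header or variable declarations do not match the schema."""


class ValidationError(ValueError):
    """The file parsed, but one or more rows violate an invariant."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one covariate: quantitative, or categorical with levels."""

    name: str
    kind: str  # "quantitative" | "categorical"
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "categorical"):
            raise SchemaError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise SchemaError(f"categorical variable {self.name!r} declares no levels")


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered collection of :class:`VariableSpec` covering every covariate column."""

    variables: tuple[VariableSpec, ...]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def quantitative(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "quantitative"]

    @property
    def categorical(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "categorical"]

    def levels_of(self, name: str) -> tuple[str, ...]:
        for v in self.variables:
            if v.name == name:
                if v.levels is None:
                    raise SchemaError(f"variable {name!r} is quantitative")
                return v.levels
        raise SchemaError(f"unknown variable {name!r}")

    @classmethod
    def from_dict(cls, spec: dict) -> "CovariateSchema":
        """Build from a ``{name: {type: ..., levels: [...]}}`` mapping (YAML-friendly)."""
        out = []
        for name, decl in spec.items():
            kind = decl.get("type", "quantitative")
            levels = tuple(str(x) for x in decl.get("levels", [])) or None
            out.append(VariableSpec(name=name, kind=kind, levels=levels))
        return cls(tuple(out))

    @classmethod
    def from_yaml(cls, path) -> "CovariateSchema":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls.from_dict(spec["variables"] if "variables" in spec else spec)

    def to_dict(self) -> dict:
        out: dict = {}
        for v in self.variables:
            d: dict = {"type": v.kind}
            if v.levels:
                d["levels"] = list(v.levels)
            out[v.name] = d
        return out


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format bilateral measurement frame in place.

    Checks column presence, enum domains, positivity of values, key
    uniqueness and per-individual sex constancy.  Returns the frame with
    canonical dtypes.  Error messages carry offending row indices
    (0-based data rows, i.e. CSV line minus header).
    """
    _require_columns(df, MEASUREMENT_COLUMNS, "measurement table")
    df = df.copy()
    df["individual_id"] = df["individual_id"].astype(str)
    df["trait_id"] = df["trait_id"].astype(str)
    df["sex"] = df["sex"].astype(str)
    df["side"] = df["side"].astype(str)

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(f"invalid sex at rows {df.index[bad_sex].tolist()}")
    bad_side = ~df["side"].isin(SIDES)
    if bad_side.any():
        raise ValidationError(f"invalid side at rows {df.index[bad_side].tolist()}")

    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    bad_rep = df["replicate"].isna() | (df["replicate"] < 1) | (df["replicate"] % 1 != 0)
    if bad_rep.any():
        raise ValidationError(f"replicate must be a positive integer; rows {df.index[bad_rep].tolist()}")
    df["replicate"] = df["replicate"].astype(int)

    df["value_mm"] = pd.to_numeric(df["value_mm"], errors="coerce")
    bad_val = df["value_mm"].isna() | (df["value_mm"] <= 0)
    if bad_val.any():
        raise ValidationError(f"value_mm must be a positive number; rows {df.index[bad_val].tolist()}")

    key = ["individual_id", "trait_id", "side", "replicate"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        raise ValidationError(f"duplicate (individual, trait, side, replicate) keys at rows {df.index[dup].tolist()}")

    sex_n = df.groupby("individual_id")["sex"].nunique()
    inconsistent = sex_n[sex_n > 1].index.tolist()
    if inconsistent:
        raise ValidationError(f"inconsistent sex for individuals {inconsistent}")
    return df


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a bilateral measurement CSV (UTF-8, comma, header)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "trait_id": str})
    return validate_measurements(df)


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_covariates(path, schema: CovariateSchema) -> pd.DataFrame:
    """Read a covariate CSV into a frame indexed by individual_id.

    Quantitative columns become float (NaN for missing); categorical
    columns become pandas ``category`` with the declared levels, missing
    cells as NaN.  Empty strings and ``NA`` both denote missing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["individual_id"] + schema.names, "covariate table")
    extra = [c for c in df.columns if c != "individual_id" and c not in schema.names]
    if extra:
        raise SchemaError(f"covariate table: undeclared columns {extra}")
    if df["individual_id"].duplicated().any():
        raise ValidationError("covariate table: duplicated individual_id")
    df = df.set_index("individual_id")
    return coerce_covariates(df, schema)


def coerce_covariates(df: pd.DataFrame, schema: CovariateSchema) -> pd.DataFrame:
    """Apply schema dtypes to a raw (string or mixed) covariate frame."""
    out = pd.DataFrame(index=df.index)
    for v in schema.variables:
        col = df[v.name]
        if col.dtype == object:
            col = col.astype(str).replace(list(NA_STRINGS), np.nan)
        if v.kind == "quantitative":
            out[v.name] = pd.to_numeric(col, errors="raise")
        else:
            col = col.astype(object).where(col.notna(), np.nan)
            observed = set(col.dropna().astype(str))
            unknown = observed - set(v.levels)  # type: ignore[arg-type]
            if unknown:
                raise ValidationError(f"variable {v.name!r}: undeclared levels {sorted(unknown)}")
            out[v.name] = pd.Categorical(col, categories=list(v.levels))  # type: ignore[arg-type]
    return out


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="individual_id", na_rep="NA")


def to_trait_table(measurements: pd.DataFrame, replicate: int = 1) -> "TraitTable":
    """Collapse a measurement table to per-individual, per-trait asymmetries.

    For each (individual, trait) with both sides present at ``replicate``:
    signed difference d = R − L, unsigned |d| and mean size (R + L)/2,
    all in mm.  Cells with a missing side are absent, never zero.
    """
    m = measurements[measurements["replicate"] == replicate]
    if m.empty:
        raise ValidationError(f"replicate {replicate} absent from the measurement table")
    wide = m.pivot_table(
        index=["individual_id", "trait_id"], columns="side", values="value_mm", aggfunc="first"
    )
    for s in SIDES:
        if s not in wide.columns:
            wide[s] = np.nan
    wide = wide.dropna(subset=["L", "R"])
    d = wide["R"] - wide["L"]
    table = pd.DataFrame(
        {"d": d, "abs_d": d.abs(), "size": (wide["R"] + wide["L"]) / 2.0}
    ).reset_index()
    sex = measurements.drop_duplicates("individual_id").set_index("individual_id")["sex"]
    table["sex"] = table["individual_id"].map(sex).values
    return TraitTable(table)


@dataclass
class TraitTable:
    """Long frame of per-individual, per-trait signed/unsigned asymmetry and size.

    Columns: individual_id, trait_id, d (= R − L, mm), abs_d, size
    (= (R+L)/2, mm), sex.
    """

    data: pd.DataFrame = field(repr=False)

    @property
    def trait_ids(self) -> list[str]:
        return sorted(self.data["trait_id"].unique())

    @property
    def individual_ids(self) -> list[str]:
        return sorted(self.data["individual_id"].unique())

    def for_trait(self, trait_id: str) -> pd.DataFrame:
        return self.data[self.data["trait_id"] == trait_id]

    def abs_d_wide(self) -> pd.DataFrame:
        """Individuals × traits matrix of unsigned asymmetries (NaN = unobserved)."""
        return self.data.pivot_table(index="individual_id", columns="trait_id", values="abs_d", aggfunc="first")

    def drop_cells(self, cells: list[tuple[str, str]]) -> "TraitTable":
        """Remove (individual_id, trait_id) cells, e.g. confirmed outliers."""
        if not cells:
            return self
        keys = set(cells)
        mask = [
            (i, t) not in keys
            for i, t in zip(self.data["individual_id"], self.data["trait_id"])
        ]
        return TraitTable(self.data[mask].reset_index(drop=True))


def missingness_report(cov: pd.DataFrame, flag_threshold: float = 0.05) -> pd.DataFrame:
    """Per-variable missing counts/fractions, flagging any above ``flag_threshold``."""
    n = len(cov)
    counts = cov.isna().sum()
    frac = counts / n if n else counts * np.nan
    return pd.DataFrame(
        {"n_missing": counts.astype(int), "fraction": frac, "flagged": frac > flag_threshold}
    )
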