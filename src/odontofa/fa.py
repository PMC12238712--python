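"""Composite fluctuating-asymmetry index.

Per-trait unsigned asymmetries |R − L| are z-standardized over the full
sample of individuals observed for that trait, averaged within each
individual over their observed traits, and the resulting composite is
z-standardized across the individuals who meet the minimum-trait rule.
Individuals whose composite exceeds the cutoff (default z > 1, strict)
are dichotomized as 'high FA'; everyone else is 'low/average'.

Averaging over observed traits rather than requiring completeness keeps
individuals with partial dentitions, but a minimum number of traits —
half the trait battery, rounded up — is required so that a composite
built from a handful of traits cannot dominate the tails.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import TraitTable


class EmptyResultError(ValueError):
    """No individual qualifies for the composite index."""


def standardize_trait_asymmetry(abs_d: np.ndarray) -> np.ndarray:
    """z-standardize one trait's |R − L| over all individuals observed for it.

    Uses the sample standard deviation (n − 1).  A zero-variance trait
    carries no asymmetry information and is dropped by the caller; this
    function raises for it.
    """
    abs_d = np.asarray(abs_d, float)
    if abs_d.size < 2:
        raise ValueError("standardization needs n >= 2")
    sd = abs_d.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(abs_d).max())):
        raise ZeroDivisionError("zero-variance trait")
    return (abs_d - abs_d.mean()) / sd


def min_trait_threshold(n_traits: int) -> int:
    """Minimum observed traits for inclusion: half the battery, rounded up."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return math.ceil(n_traits / 2)


def dichotomize(composite_z: float, cutoff: float = 1.0) -> int:
    """1 iff the z-standardized composite strictly exceeds the cutoff."""
    if not np.isfinite(composite_z):
        raise ValueError("composite_z must be finite")
    return int(composite_z > cutoff)


@dataclass
class FAIndexResult:
    """Per-individual composite FA values and the high-FA dichotomy.

    ``table`` columns: individual_id (index), sex, n_observed_traits,
    composite_raw, composite_z (NaN when excluded), high_fa (0/1, -1 when
    excluded), included.
    """

    table: pd.DataFrame
    min_traits: int
    cutoff: float
    dropped_traits: list[str]

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]

    @property
    def n_included(self) -> int:
        return int(self.table["included"].sum())

    @property
    def n_excluded(self) -> int:
        return int((~self.table["included"]).sum())

    def high_fa_counts_by_sex(self) -> pd.DataFrame:
        """2×2 contingency of high vs low/average FA by sex (included only)."""
        inc = self.included
        return pd.crosstab(inc["sex"], inc["high_fa"]).reindex(columns=[1, 0], fill_value=0)


def compute_fa_index(
    traits: TraitTable,
    trait_ids: list[str] | None = None,
    min_traits: int | None = None,
    cutoff: float = 1.0,
) -> FAIndexResult:
    """Build the composite FA index from (screened) per-trait asymmetries.

    Parameters
    ----------
    traits
        Cleaned trait table (outliers removed, excluded traits dropped).
    trait_ids
        Trait battery to use; defaults to every trait present.  Alternate
        batteries (e.g. deciduous mesiodistal/buccolingual or
        gestational-window trait sets) are just different lists here.
    min_traits
        Inclusion threshold; defaults to ``ceil(len(battery)/2)``.
    cutoff
        High-FA cutoff on the z-standardized composite (strict >).
    """
    wide = traits.abs_d_wide()
    if trait_ids is not None:
        missing = [t for t in trait_ids if t not in wide.columns]
        if missing:
            raise KeyError(f"traits absent from table: {missing}")
        wide = wide[trait_ids]

    dropped: list[str] = []
    z = {}
    for t in wide.columns:
        col = wide[t].dropna()
        if col.size < 2 or col.std(ddof=1) <= 1e-12 * max(1.0, float(col.abs().max())):
            dropped.append(t)
            warnings.warn(f"trait {t!r} dropped from FA index (zero variance or n < 2)")
            continue
        z[t] = (wide[t] - col.mean()) / col.std(ddof=1)
    if not z:
        raise EmptyResultError("no usable traits")
    zmat = pd.DataFrame(z)

    if min_traits is None:
        min_traits = min_trait_threshold(zmat.shape[1])

    n_obs = zmat.notna().sum(axis=1)
    composite_raw = zmat.mean(axis=1, skipna=True)
    included = n_obs >= min_traits
    if not included.any():
        raise EmptyResultError(f"no individual has >= {min_traits} observed traits")

    inc_vals = composite_raw[included]
    composite_z = pd.Series(np.nan, index=composite_raw.index)
    composite_z[included] = (inc_vals - inc_vals.mean()) / inc_vals.std(ddof=1)

    sex = traits.data.drop_duplicates("individual_id").set_index("individual_id")["sex"]
    table = pd.DataFrame(
        {
            "sex": sex.reindex(composite_raw.index),
            "n_observed_traits": n_obs.astype(int),
            "composite_raw": composite_raw,
            "composite_z": composite_z,
            "included": included,
        }
    )
    table["high_fa"] = np.where(included, (composite_z > cutoff).astype(int), -1)
    return FAIndexResult(table=table, min_traits=min_traits, cutoff=cutoff, dropped_traits=dropped)
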