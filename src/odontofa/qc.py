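"""Pre-index screening battery for bilateral traits.

Before a fluctuating-asymmetry (FA) index can be interpreted as
developmental instability, each trait must be screened for the classical
confounders of asymmetry analysis: intra-observer bias between replicate
measurements, measurement error large relative to the asymmetry signal,
outlying raw values, directional asymmetry (nonzero mean of signed R − L),
antisymmetry (platykurtic / bimodal R − L), and dependence of |R − L| on
trait size.  Each screen is a small, separately testable function;
:func:`run_screen` applies the whole battery per trait, Holm-adjusts the
p-values within each test family across traits, and emits one
:class:`TraitScreenReport` per trait.

Only the error screens (replicate bias, error-vs-asymmetry) and a
low-presence rule force exclusion by default; distributional screens are
reported, and can be made exclusionary through :class:`ScreenConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import TraitTable


def _effectively_constant(x: np.ndarray) -> bool:
    """Guard for zero-variance vectors robust to float summation noise."""
    x = np.asarray(x, float)
    scale = max(1.0, float(np.max(np.abs(x))) if x.size else 1.0)
    return float(x.std(ddof=1)) <= 1e-12 * scale


class InsufficientDataError(ValueError):
    """Too few observations for the requested test."""


@dataclass
class TestResult:
    statistic: float
    p: float
    df: float | None = None
    flag: str | None = None  # e.g. "exact_bias", "degenerate", "skipped"


def replicate_bias_test(first: np.ndarray, second: np.ndarray) -> TestResult:
    """Paired two-sided t-test of replicate 2 against replicate 1.

    A significant result indicates systematic intra-observer bias for the
    trait.  Zero variance of the differences with a nonzero mean is an
    exact bias (every remeasurement shifted identically) and is flagged
    rather than divided by zero.
    """
    first = np.asarray(first, float)
    second = np.asarray(second, float)
    if first.shape != second.shape:
        raise ValueError("replicate vectors must be paired (equal length)")
    n = first.size
    if n < 3:
        raise InsufficientDataError(f"paired t-test needs n >= 3, got {n}")
    diff = second - first
    if _effectively_constant(diff):
        if abs(diff.mean()) <= 1e-12 * max(1.0, np.abs(first).max()):
            return TestResult(statistic=0.0, p=1.0, df=n - 1)
        return TestResult(statistic=np.inf, p=0.0, df=n - 1, flag="exact_bias")
    sd = diff.std(ddof=1)
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(statistic=float(t), p=float(p), df=n - 1)


@dataclass
class ErrorScreenResult:
    mean_me: float
    mean_fa: float
    exclude: bool


def error_vs_asymmetry_screen(replicate_abs_diff: np.ndarray, abs_asymmetry: np.ndarray) -> ErrorScreenResult:
    """Exclude a trait when mean measurement error exceeds mean unsigned asymmetry.

    ``replicate_abs_diff`` are per-measurement |m2 − m1| from the
    replicate subset; ``abs_asymmetry`` are |R − L| over the full sample.
    The comparison is a strict inequality: a trait whose error equals its
    asymmetry is retained.
    """
    me = np.asarray(replicate_abs_diff, float)
    fa = np.asarray(abs_asymmetry, float)
    if me.size == 0 or fa.size == 0:
        raise InsufficientDataError("error screen needs non-empty inputs")
    mean_me = float(me.mean())
    mean_fa = float(fa.mean())
    return ErrorScreenResult(mean_me=mean_me, mean_fa=mean_fa, exclude=mean_me > mean_fa)


@dataclass
class GrubbsResult:
    outlier_indices: list[int]
    g_values: list[float]
    critical_values: list[float]
    degenerate: bool = False


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_scan(d: np.ndarray, alpha: float = 0.05) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier scan on signed asymmetries.

    Repeatedly tests the most extreme point against the Grubbs critical
    value; on rejection the point is removed and the test repeated on
    the reduced sample.  Indices are reported in removal order and refer
    to the original vector.
    """
    d = np.asarray(d, float)
    if d.size < 3:
        raise InsufficientDataError(f"Grubbs scan needs n >= 3, got {d.size}")
    live = list(range(d.size))
    out: list[int] = []
    gs: list[float] = []
    crits: list[float] = []
    while len(live) >= 3:
        vals = d[live]
        if _effectively_constant(vals):
            return GrubbsResult(out, gs, crits, degenerate=not out)
        s = vals.std(ddof=1)
        dev = np.abs(vals - vals.mean())
        i_max = int(np.argmax(dev))
        g = float(dev[i_max] / s)
        crit = grubbs_critical(len(live), alpha)
        if g > crit:
            out.append(live.pop(i_max))
            gs.append(g)
            crits.append(crit)
        else:
            break
    return GrubbsResult(out, gs, crits)


def directional_asymmetry_test(d: np.ndarray) -> TestResult:
    """One-sample two-sided t-test of mean(R − L) against zero.

    A significant nonzero mean is directional asymmetry: one side is
    systematically larger, which contaminates an FA index.
    """
    d = np.asarray(d, float)
    if d.size < 3:
        raise InsufficientDataError(f"DA test needs n >= 3, got {d.size}")
    if _effectively_constant(d):
        return TestResult(statistic=0.0, p=1.0, df=d.size - 1, flag="degenerate")
    t, p = stats.ttest_1samp(d, 0.0)
    return TestResult(statistic=float(t), p=float(p), df=d.size - 1)


@dataclass
class AntisymmetryResult:
    kurtosis_statistic: float
    kurtosis_p: float
    excess_kurtosis: float
    omnibus_p: float
    flagged: bool  # platykurtosis significant in the negative direction
    flag: str | None = None


def antisymmetry_test(d: np.ndarray, alpha: float = 0.05) -> AntisymmetryResult:
    """Screen signed asymmetries for antisymmetry.

    Antisymmetry — one side consistently larger but randomly which —
    produces a bimodal, hence platykurtic, distribution of R − L.  The
    screen combines a moment-based kurtosis test with an omnibus
    normality test; antisymmetry is flagged only when the kurtosis test
    is significant *and* the sample excess kurtosis is negative, since
    leptokurtosis does not indicate bimodality.  The direction is read
    from the sample excess kurtosis rather than the sign of the z
    statistic, whose normalizing transform is unreliable near the
    platykurtic boundary (excess kurtosis close to −2).
    """
    d = np.asarray(d, float)
    if d.size < 8:
        raise InsufficientDataError(f"antisymmetry screen needs n >= 8, got {d.size}")
    if _effectively_constant(d):
        return AntisymmetryResult(0.0, 1.0, 0.0, 1.0, False, flag="degenerate")
    kz, kp = stats.kurtosistest(d)
    _, op = stats.normaltest(d)
    g2 = float(stats.kurtosis(d))
    flagged = bool(g2 < 0 and kp < alpha)
    return AntisymmetryResult(float(kz), float(kp), g2, float(op), flagged)


@dataclass
class SizeDependenceResult:
    rho: float | None
    p: float | None
    flag: str | None = None


def size_dependence_test(
    abs_d: np.ndarray,
    size: np.ndarray,
    groups: np.ndarray | None = None,
    min_n: int = 5,
) -> dict[str, SizeDependenceResult]:
    """Spearman correlation of |R − L| with trait size, pooled and per group.

    Average ranks are used for ties; groups (typically sexes) below
    ``min_n`` observations are skipped with a reason code, and constant
    vectors yield an undefined-correlation flag rather than a value.
    """
    abs_d = np.asarray(abs_d, float)
    size = np.asarray(size, float)
    if abs_d.shape != size.shape:
        raise ValueError("abs_d and size must be paired")

    def one(a: np.ndarray, s: np.ndarray) -> SizeDependenceResult:
        if a.size < min_n:
            return SizeDependenceResult(None, None, flag="insufficient_n")
        if np.all(a == a[0]) or np.all(s == s[0]):
            return SizeDependenceResult(None, None, flag="constant_input")
        rho, p = stats.spearmanr(a, s)
        return SizeDependenceResult(float(rho), float(p))

    out = {"pooled": one(abs_d, size)}
    if groups is not None:
        groups = np.asarray(groups)
        for g in sorted(pd.unique(groups)):
            m = groups == g
            out[str(g)] = one(abs_d[m], size[m])
    return out


def holm_correct(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down (sequential Bonferroni) adjustment.

    Returns (adjusted p-values, reject flags) in input order.  NaNs pass
    through unadjusted and are never rejected (they do not count toward
    the family size).
    """
    p = np.asarray(p, float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    rej = np.zeros_like(p, bool)
    if finite.sum():
        r, a, _, _ = multipletests(p[finite], alpha=alpha, method="holm")
        adj[finite] = a
        rej[finite] = r
    return adj, rej


@dataclass
class ScreenConfig:
    alpha: float = 0.05
    grubbs_alpha: float = 0.05
    min_presence_fraction: float = 0.25  # trait retained only if observed in >= this share
    remove_outliers: bool = True
    distributional_exclusions: bool = False  # DA / antisymmetry / size screens exclude


@dataclass
class TraitScreenReport:
    trait_id: str
    n_observed: int
    replicate_bias: TestResult | None
    mean_measurement_error: float | None
    mean_unsigned_asymmetry: float
    error_exceeds_asymmetry: bool
    outlier_ids: list[str]
    da_test: TestResult | None
    antisymmetry: AntisymmetryResult | None
    size_dependence: dict[str, SizeDependenceResult]
    holm_adjusted_p: dict[str, float] = field(default_factory=dict)
    retained: bool = True
    reasons: list[str] = field(default_factory=list)


@dataclass
class ScreenResult:
    reports: list[TraitScreenReport]
    removed_cells: list[tuple[str, str]]  # (individual_id, trait_id) outlier cells
    cleaned: TraitTable

    @property
    def retained_traits(self) -> list[str]:
        return [r.trait_id for r in self.reports if r.retained]

    def summary(self) -> str:
        n = len(self.reports)
        err = sum("measurement_error" in r.reasons or "replicate_bias" in r.reasons for r in self.reports)
        low = sum("low_presence" in r.reasons for r in self.reports)
        kept = len(self.retained_traits)
        return f"screened {n} traits: {err} excluded by error screens, {low} by low presence, {kept} retained"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            pooled = r.size_dependence.get("pooled", SizeDependenceResult(None, None))
            rows.append(
                {
                    "trait_id": r.trait_id,
                    "n_observed": r.n_observed,
                    "replicate_bias_t": r.replicate_bias.statistic if r.replicate_bias else np.nan,
                    "replicate_bias_p": r.replicate_bias.p if r.replicate_bias else np.nan,
                    "replicate_bias_p_holm": r.holm_adjusted_p.get("replicate_bias", np.nan),
                    "mean_measurement_error": np.nan if r.mean_measurement_error is None else r.mean_measurement_error,
                    "mean_unsigned_asymmetry": r.mean_unsigned_asymmetry,
                    "error_exceeds_asymmetry": r.error_exceeds_asymmetry,
                    "n_outliers": len(r.outlier_ids),
                    "da_t": r.da_test.statistic if r.da_test else np.nan,
                    "da_p": r.da_test.p if r.da_test else np.nan,
                    "da_p_holm": r.holm_adjusted_p.get("da", np.nan),
                    "antisymmetry_kurtosis_z": r.antisymmetry.kurtosis_statistic if r.antisymmetry else np.nan,
                    "antisymmetry_p": r.antisymmetry.kurtosis_p if r.antisymmetry else np.nan,
                    "antisymmetry_p_holm": r.holm_adjusted_p.get("antisymmetry", np.nan),
                    "size_rho": np.nan if pooled.rho is None else pooled.rho,
                    "size_p": np.nan if pooled.p is None else pooled.p,
                    "size_p_holm": r.holm_adjusted_p.get("size", np.nan),
                    "retained": r.retained,
                    "reasons": ";".join(r.reasons),
                }
            )
        return pd.DataFrame(rows)


def _replicate_pairs(measurements: pd.DataFrame, trait_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-individual (replicate-1, replicate-2) values for one trait.

    Sides are averaged within each individual and session before
    pairing: session-level error components are shared by the two sides
    of a trait, so treating L and R as independent pairs would
    double-count them and inflate the bias test's type-I error.
    """
    m = measurements[measurements["trait_id"] == trait_id]
    wide = m.pivot_table(index="individual_id", columns="replicate", values="value_mm", aggfunc="mean")
    if 1 not in wide.columns or 2 not in wide.columns:
        return np.array([]), np.array([])
    wide = wide.dropna(subset=[1, 2])
    return wide[1].to_numpy(), wide[2].to_numpy()


def run_screen(
    traits: TraitTable,
    measurements: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Apply the full screening battery to every trait.

    Per trait: replicate bias t-test and error-vs-asymmetry comparison on
    the replicate subset; Grubbs outlier scan on signed asymmetries (with
    cell-level removal when configured); directional-asymmetry,
    antisymmetry and size-dependence tests on the cleaned values.
    p-values are then Holm-adjusted across traits within each test
    family, and exclusion verdicts assembled.
    """
    cfg = config or ScreenConfig()
    n_individuals = len(traits.individual_ids)
    min_obs = cfg.min_presence_fraction * n_individuals

    reports: list[TraitScreenReport] = []
    removed: list[tuple[str, str]] = []

    for trait_id in traits.trait_ids:
        tdf = traits.for_trait(trait_id)
        d = tdf["d"].to_numpy()
        ids = tdf["individual_id"].to_numpy()

        first, second = _replicate_pairs(measurements, trait_id)
        rep_bias = None
        mean_me = None
        err_exceeds = False
        if first.size >= 3:
            rep_bias = replicate_bias_test(first, second)
            screen = error_vs_asymmetry_screen(np.abs(second - first), np.abs(d))
            mean_me = screen.mean_me
            err_exceeds = screen.exclude

        outlier_ids: list[str] = []
        if cfg.remove_outliers and d.size >= 3:
            g = grubbs_scan(d, cfg.grubbs_alpha)
            outlier_ids = [str(ids[i]) for i in g.outlier_indices]
            removed.extend((oid, trait_id) for oid in outlier_ids)
            keep = np.ones(d.size, bool)
            keep[g.outlier_indices] = False
            tdf = tdf[keep]
            d = d[keep]

        da = directional_asymmetry_test(d) if d.size >= 3 else None
        anti = antisymmetry_test(d, cfg.alpha) if d.size >= 8 else None
        sized = (
            size_dependence_test(tdf["abs_d"].to_numpy(), tdf["size"].to_numpy(), tdf["sex"].to_numpy())
            if d.size >= 5
            else {}
        )

        reports.append(
            TraitScreenReport(
                trait_id=trait_id,
                n_observed=int(d.size),
                replicate_bias=rep_bias,
                mean_measurement_error=mean_me,
                mean_unsigned_asymmetry=float(np.abs(d).mean()) if d.size else np.nan,
                error_exceeds_asymmetry=err_exceeds,
                outlier_ids=outlier_ids,
                da_test=da,
                antisymmetry=anti,
                size_dependence=sized,
            )
        )

    # Holm families: one family per test kind, across traits
    families = {
        "replicate_bias": [r.replicate_bias.p if r.replicate_bias else np.nan for r in reports],
        "da": [r.da_test.p if r.da_test else np.nan for r in reports],
        "antisymmetry": [r.antisymmetry.kurtosis_p if r.antisymmetry else np.nan for r in reports],
        "size": [
            r.size_dependence["pooled"].p
            if "pooled" in r.size_dependence and r.size_dependence["pooled"].p is not None
            else np.nan
            for r in reports
        ],
    }
    rejections: dict[str, np.ndarray] = {}
    for fam, ps in families.items():
        adj, rej = holm_correct(np.array(ps, float), cfg.alpha)
        rejections[fam] = rej
        for r, a in zip(reports, adj):
            if not np.isnan(a):
                r.holm_adjusted_p[fam] = float(a)

    for i, r in enumerate(reports):
        reasons = []
        if r.replicate_bias is not None and (
            rejections["replicate_bias"][i] or r.replicate_bias.flag == "exact_bias"
        ):
            reasons.append("replicate_bias")
        if r.error_exceeds_asymmetry:
            reasons.append("measurement_error")
        if r.n_observed < min_obs:
            reasons.append("low_presence")
        if cfg.distributional_exclusions:
            for fam, code in (("da", "directional_asymmetry"), ("size", "size_dependence")):
                if rejections[fam][i]:
                    reasons.append(code)
            if r.antisymmetry is not None and rejections["antisymmetry"][i] and r.antisymmetry.excess_kurtosis < 0:
                reasons.append("antisymmetry")
        r.reasons = reasons
        r.retained = not reasons

    cleaned = traits.drop_cells(removed)
    retained = {r.trait_id for r in reports if r.retained}
    cleaned = TraitTable(cleaned.data[cleaned.data["trait_id"].isin(retained)].reset_index(drop=True))
    return ScreenResult(reports=reports, removed_cells=removed, cleaned=cleaned)
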