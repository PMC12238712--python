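"""Synthetic cohort generator with known ground truth.

Generates complete study-shaped inputs — a long-format bilateral
measurement table, a mixed covariate table, and the latent truth behind
both — so every pipeline stage can be validated against quantities that
are known exactly.

The generative model:

* each individual carries a 4-vector of latent early-life factors
  z ~ N(0, I);
* 21 mixed covariates (6 quantitative, 15 categorical) load on those
  factors: a variable's latent propensity is u = L'z + noise with unit
  variance, quantitative values are affine in u, categorical levels are
  u thresholded at normal quantiles matching target level frequencies;
* developmental instability scales multiplicatively:
  s_i = exp(sum_d beta_{d, sex(i)} z_{id} + tau * eps_i), with a
  sex-independent developmental-noise term tau*eps_i (unmeasured
  sources of instability) so both sexes populate the high-FA tail;
  negative female-only coefficients on factors 2 and 4 make those
  factors protective in females and inert in males;
* per trait, the signed asymmetry is d ~ N(DA_t, (sigma_t s_i)^2) (or a
  symmetric two-mode mixture when antisymmetry is injected), sides are
  L = T − d/2 and R = T + d/2 around a trait size T ~ N(size_t,
  sigma_size^2);
* every recorded measurement adds observer error with a session-shared
  component (landmark re-identification between measurement sessions)
  and an independent per-event component; the session component cancels
  from same-session |R − L| but not from between-session replicate
  differences, which is what lets an error-inflated trait fail the
  error-versus-asymmetry screen;
* the designated replicate subset is measured in a second session;
  missing-completely-at-random masks are applied to covariate cells and
  to measurement cells, the latter with a small 'poor cast' subgroup of
  individuals with heavy trait missingness.

All randomness flows from one integer seed through named
``SeedSequence`` child streams (covariates, asymmetry, sides, error,
missingness), so adding draws to one component does not shift another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import CovariateSchema, VariableSpec, validate_measurements


@dataclass(frozen=True)
class CovariateSimSpec:
    """How one synthetic covariate is produced from the latent factors."""

    name: str
    kind: str  # "quantitative" | "categorical"
    loadings: tuple[float, float, float, float]
    mean: float = 0.0
    sd: float = 1.0
    levels: tuple[str, ...] = ()
    frequencies: tuple[float, ...] = ()


def default_covariate_specs() -> list[CovariateSimSpec]:
    """The 21-variable battery of parental, gestational and childhood
    covariates, with level frequencies in the vicinity of a 1950s
    Ontario growth cohort (e.g. ~42% of infants breastfed, ~89% born at
    term) and thematic factor loadings: factor 1 = parental age,
    factor 2 = breastfeeding history, factor 3 = parental education/
    occupation SES, factor 4 = migration background and gestational
    condition."""
    edu_levels = (
        "lt_grade8",
        "some_high_school",
        "vocational",
        "junior_matric",
        "senior_matric",
        "some_university",
        "university",
    )
    edu_freqs = (0.18, 0.30, 0.12, 0.08, 0.11, 0.10, 0.11)
    occ_levels = (
        "business_finance",
        "sciences",
        "health",
        "education_law_social",
        "arts_culture",
        "sales_service",
        "trades_transport",
        "agriculture",
        "manufacturing",
    )
    occ_freqs = (0.10, 0.10, 0.03, 0.04, 0.03, 0.28, 0.24, 0.06, 0.12)
    return [
        CovariateSimSpec("mother_age", "quantitative", (0.85, 0.0, 0.1, 0.0), 28.9, 4.6),
        CovariateSimSpec("father_age", "quantitative", (0.80, 0.0, 0.1, 0.0), 31.8, 5.4),
        CovariateSimSpec(
            "mother_period_of_birth",
            "categorical",
            (-0.80, 0.0, 0.0, 0.0),
            levels=("prewar", "wwi", "twenties", "depression"),
            frequencies=(0.09, 0.26, 0.63, 0.02),
        ),
        CovariateSimSpec("mother_education", "categorical", (0.0, 0.0, 0.70, 0.30), levels=edu_levels, frequencies=edu_freqs),
        CovariateSimSpec("father_education", "categorical", (0.0, 0.0, 0.72, 0.30), levels=edu_levels, frequencies=edu_freqs),
        CovariateSimSpec(
            "mother_group",
            "categorical",
            (0.0, 0.0, 0.0, 0.85),
            levels=("british_french", "irish", "other_european"),
            frequencies=(0.73, 0.12, 0.15),
        ),
        CovariateSimSpec(
            "father_group",
            "categorical",
            (0.0, 0.0, 0.0, 0.85),
            levels=("british_french", "irish", "other_european"),
            frequencies=(0.72, 0.15, 0.13),
        ),
        CovariateSimSpec("father_occupation", "categorical", (0.0, 0.0, 0.55, 0.40), levels=occ_levels, frequencies=occ_freqs),
        CovariateSimSpec(
            "prior_miscarriage",
            "categorical",
            (0.25, 0.0, 0.0, 0.0),
            levels=("no", "yes"),
            frequencies=(0.78, 0.22),
        ),
        CovariateSimSpec(
            "parity",
            "categorical",
            (0.45, 0.0, 0.0, 0.0),
            levels=("nulliparous", "primiparous", "multiparous"),
            frequencies=(0.27, 0.40, 0.33),
        ),
        CovariateSimSpec("year_of_birth", "quantitative", (-0.30, 0.0, 0.0, 0.35), 1950.2, 0.95),
        CovariateSimSpec(
            "season_of_birth",
            "categorical",
            (0.0, 0.0, 0.0, 0.0),
            levels=("winter", "spring", "summer", "fall"),
            frequencies=(0.24, 0.29, 0.24, 0.23),
        ),
        CovariateSimSpec(
            "gestation_length",
            "categorical",
            (0.0, 0.0, 0.0, 0.30),
            levels=("early", "term", "late"),
            frequencies=(0.056, 0.885, 0.059),
        ),
        CovariateSimSpec("birthweight_kg", "quantitative", (0.0, 0.0, 0.0, -0.50), 3.37, 0.48),
        CovariateSimSpec(
            "breastfed",
            "categorical",
            (0.0, 0.85, 0.0, 0.0),
            levels=("no", "yes"),
            frequencies=(0.58, 0.42),
        ),
        CovariateSimSpec(
            "breastfed_duration",
            "categorical",
            (0.0, 0.88, 0.0, 0.0),
            levels=("none", "lt_1mo", "1_2mo", "2_6mo", "6mo_plus"),
            frequencies=(0.57, 0.08, 0.11, 0.10, 0.14),
        ),
        CovariateSimSpec(
            "formula_type",
            "categorical",
            (0.0, -0.70, 0.0, 0.0),
            levels=("none_breastfed", "homemade", "manufactured"),
            frequencies=(0.11, 0.74, 0.15),
        ),
        CovariateSimSpec(
            "sick_before_1yr",
            "categorical",
            (0.0, 0.0, -0.20, 0.0),
            levels=("no", "yes"),
            frequencies=(0.92, 0.08),
        ),
        CovariateSimSpec(
            "sick_before_3yr",
            "categorical",
            (0.0, 0.0, -0.25, 0.0),
            levels=("no", "yes"),
            frequencies=(0.46, 0.54),
        ),
        CovariateSimSpec("fa_deciduous_mdbl", "quantitative", (0.0, 0.0, 0.0, -0.60), 0.0, 1.0),
        CovariateSimSpec("fa_deciduous_gest", "quantitative", (0.0, 0.0, 0.0, -0.60), 0.0, 1.0),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_males: int = 154
    n_females: int = 149
    n_traits: int = 20
    n_latent: int = 4
    # trait geometry (mm): intercuspal distances span roughly 2-7 mm
    size_min_mm: float = 2.0
    size_max_mm: float = 7.0
    sigma_size: float = 0.30  # between-individual trait size sd (mm)
    sigma_fa: float = 0.12  # baseline per-trait FA sd (mm)
    # observer error (mm): session-shared + independent per event
    sigma_session: float = 0.02
    sigma_event: float = 0.03
    replicate_subset: int = 30
    # sex-specific instability coefficients on latent factors
    beta_female: tuple[float, float, float, float] = (0.0, -0.25, 0.0, -0.30)
    beta_male: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    # sd of the sex-independent log-instability noise (unmeasured factors)
    sigma_instability: float = 0.30
    # missingness
    covariate_mcar: float = 0.03
    measurement_mcar: float = 0.095
    poor_cast_fraction: float = 0.028
    poor_cast_mcar: float = 0.60
    # per-trait pathology overrides (filled by inject_pathology)
    sigma_session_override: dict[str, float] = field(default_factory=dict)
    da_shift: dict[str, float] = field(default_factory=dict)
    antisymmetry_mode: dict[str, float] = field(default_factory=dict)
    size_dependence: dict[str, float] = field(default_factory=dict)
    trait_presence: dict[str, float] = field(default_factory=dict)
    covariates: list[CovariateSimSpec] = field(default_factory=default_covariate_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1 or self.n_traits < 1:
            raise ValueError("cohort and trait counts must be positive")
        if self.sigma_instability < 0:
            raise ValueError("sigma_instability must be >= 0")
        for name, v in (
            ("sigma_size", self.sigma_size),
            ("sigma_fa", self.sigma_fa),
            ("sigma_session", self.sigma_session),
            ("sigma_event", self.sigma_event),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        for name, r in (
            ("covariate_mcar", self.covariate_mcar),
            ("measurement_mcar", self.measurement_mcar),
            ("poor_cast_fraction", self.poor_cast_fraction),
            ("poor_cast_mcar", self.poor_cast_mcar),
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.replicate_subset > self.n_males + self.n_females:
            raise ValueError("replicate subset exceeds cohort size")
        for spec in self.covariates:
            if len(spec.loadings) != self.n_latent:
                raise ValueError(f"covariate {spec.name}: loading length != n_latent")
            if spec.kind == "categorical" and abs(sum(spec.frequencies) - 1.0) > 1e-8:
                raise ValueError(f"covariate {spec.name}: level frequencies must sum to 1")
        known = set(self.trait_ids)
        for d in (
            self.sigma_session_override,
            self.da_shift,
            self.antisymmetry_mode,
            self.size_dependence,
            self.trait_presence,
        ):
            unknown = set(d) - known
            if unknown:
                raise ValueError(f"pathology refers to unknown traits {sorted(unknown)}")

    @property
    def n_individuals(self) -> int:
        return self.n_males + self.n_females

    @property
    def trait_ids(self) -> list[str]:
        return [f"t{k + 1:02d}" for k in range(self.n_traits)]

    @property
    def trait_sizes(self) -> np.ndarray:
        if self.n_traits == 1:
            return np.array([(self.size_min_mm + self.size_max_mm) / 2.0])
        return np.linspace(self.size_min_mm, self.size_max_mm, self.n_traits)

    def schema(self) -> CovariateSchema:
        return CovariateSchema(
            tuple(
                VariableSpec(s.name, s.kind, s.levels or None) for s in self.covariates
            )
        )


PATHOLOGY_KINDS = ("measurement_error", "DA", "antisymmetry", "size_dependence", "low_presence")


def inject_pathology(
    config: SimulationConfig, kind: str, traits: list[str], magnitude: float
) -> SimulationConfig:
    """Return a config whose flagged traits violate exactly one assumption.

    * ``measurement_error``: session error sd set to ``magnitude x
      sigma_fa`` (so magnitude 3 gives error well above asymmetry);
    * ``DA``: mean of signed asymmetry shifted by ``magnitude`` mm;
    * ``antisymmetry``: d replaced by a symmetric two-mode mixture at
      ``±magnitude`` mm;
    * ``size_dependence``: asymmetry sd coupled to trait size with
      exponent ``magnitude``;
    * ``low_presence``: trait observed with probability ``magnitude``.
    """
    if kind not in PATHOLOGY_KINDS:
        raise ValueError(f"unknown pathology kind {kind!r}; one of {PATHOLOGY_KINDS}")
    unknown = set(traits) - set(config.trait_ids)
    if unknown:
        raise ValueError(f"unknown traits {sorted(unknown)}")
    if magnitude == 0.0 and kind in ("DA", "size_dependence"):
        return config
    updates: dict = {}
    if kind == "measurement_error":
        updates["sigma_session_override"] = {
            **config.sigma_session_override,
            **{t: magnitude * config.sigma_fa for t in traits},
        }
    elif kind == "DA":
        updates["da_shift"] = {**config.da_shift, **{t: magnitude for t in traits}}
    elif kind == "antisymmetry":
        updates["antisymmetry_mode"] = {
            **config.antisymmetry_mode,
            **{t: magnitude for t in traits},
        }
    elif kind == "size_dependence":
        updates["size_dependence"] = {
            **config.size_dependence,
            **{t: magnitude for t in traits},
        }
    else:
        updates["trait_presence"] = {
            **config.trait_presence,
            **{t: magnitude for t in traits},
        }
    return replace(config, **updates)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort, for recovery tests."""

    latent: pd.DataFrame  # n x n_latent factor scores, index individual_id
    instability: pd.Series  # s_i = baseline_i * exp(beta . z), per individual
    baseline: pd.Series  # exp(tau * eps_i), the unmeasured-noise factor
    sex: pd.Series
    beta_female: tuple[float, ...]
    beta_male: tuple[float, ...]
    pathologies: dict[str, dict[str, float]]
    covariates_complete: pd.DataFrame  # pre-missingness covariate values


@dataclass
class SyntheticCohort:
    measurements: pd.DataFrame
    covariates: pd.DataFrame
    schema: CovariateSchema
    truth: SyntheticTruth


def _simulate_covariates(
    specs: list[CovariateSimSpec], z: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n = z.shape[0]
    out = {}
    for spec in specs:
        load = np.asarray(spec.loadings)
        ss = float(load @ load)
        if ss > 0.95:
            load = load * np.sqrt(0.95 / ss)
            ss = 0.95
        u = z @ load + rng.standard_normal(n) * np.sqrt(1.0 - ss)
        if spec.kind == "quantitative":
            out[spec.name] = spec.mean + spec.sd * u
        else:
            from scipy.stats import norm

            cuts = norm.ppf(np.cumsum(spec.frequencies)[:-1])
            idx = np.searchsorted(cuts, u)
            out[spec.name] = np.array(spec.levels, object)[idx]
    return pd.DataFrame(out)


def generate(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; byte-identical under a fixed seed."""
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("latent", "covariates", "asymmetry", "sides", "error", "missing"),
            root.spawn(6),
        )
    }
    n = config.n_individuals
    ids = np.array([f"I{k + 1:04d}" for k in range(n)])
    sex = np.array(["M"] * config.n_males + ["F"] * config.n_females)
    streams["latent"].shuffle(sex)

    z = streams["latent"].standard_normal((n, config.n_latent))
    beta = np.where(
        (sex == "F")[:, None], np.asarray(config.beta_female), np.asarray(config.beta_male)
    )
    baseline = np.exp(config.sigma_instability * streams["latent"].standard_normal(n))
    s = baseline * np.exp(np.sum(beta * z, axis=1))

    covariates = _simulate_covariates(config.covariates, z, streams["covariates"])
    covariates.index = pd.Index(ids, name="individual_id")
    cov_complete = covariates.copy()

    # --- bilateral measurements ---------------------------------------
    T = config.n_traits
    sizes = config.trait_sizes
    da = np.array([config.da_shift.get(t, 0.0) for t in config.trait_ids])
    anti = np.array([config.antisymmetry_mode.get(t, 0.0) for t in config.trait_ids])
    size_dep = np.array([config.size_dependence.get(t, 0.0) for t in config.trait_ids])
    sess_sd = np.array(
        [config.sigma_session_override.get(t, config.sigma_session) for t in config.trait_ids]
    )
    presence = np.array([config.trait_presence.get(t, 1.0) for t in config.trait_ids])

    true_size = sizes[None, :] + streams["sides"].standard_normal((n, T)) * config.sigma_size
    sd_d = config.sigma_fa * s[:, None] * np.power(
        np.clip(true_size / sizes[None, :], 0.1, None), size_dep[None, :]
    )
    d = da[None, :] + streams["asymmetry"].standard_normal((n, T)) * sd_d
    if np.any(anti > 0):
        signs = streams["asymmetry"].choice([-1.0, 1.0], size=(n, T))
        mix = signs * anti[None, :] + streams["asymmetry"].standard_normal((n, T)) * sd_d
        d = np.where(anti[None, :] > 0, mix, d)
    left_true = true_size - d / 2.0
    right_true = true_size + d / 2.0

    rep_ids = streams["missing"].choice(n, size=config.replicate_subset, replace=False)
    in_subset = np.zeros(n, bool)
    in_subset[rep_ids] = True

    # observed trait mask: per-individual MCAR (with poor-cast subgroup)
    # and per-trait presence
    poor = streams["missing"].random(n) < config.poor_cast_fraction
    rate = np.where(poor, config.poor_cast_mcar, config.measurement_mcar)
    observed = streams["missing"].random((n, T)) >= rate[:, None]
    observed &= streams["missing"].random((n, T)) < presence[None, :]

    err = streams["error"]
    frames = []
    for session in (1, 2):
        mask = observed if session == 1 else observed & in_subset[:, None]
        if not mask.any():
            continue
        shift = err.standard_normal((n, T)) * sess_sd[None, :]
        for side, true_vals in (("L", left_true), ("R", right_true)):
            vals = true_vals + shift + err.standard_normal((n, T)) * config.sigma_event
            ii, tt = np.nonzero(mask)
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": ids[ii],
                        "sex": sex[ii],
                        "trait_id": np.array(config.trait_ids)[tt],
                        "side": side,
                        "replicate": session,
                        "value_mm": np.clip(vals[ii, tt], 0.01, None),
                    }
                )
            )
    measurements = pd.concat(frames, ignore_index=True)
    measurements = measurements.sort_values(
        ["individual_id", "trait_id", "side", "replicate"], kind="mergesort"
    ).reset_index(drop=True)
    measurements = validate_measurements(measurements)

    if config.covariate_mcar > 0:
        mask = streams["missing"].random(covariates.shape) < config.covariate_mcar
        covariates = covariates.mask(pd.DataFrame(mask, index=covariates.index, columns=covariates.columns))

    truth = SyntheticTruth(
        latent=pd.DataFrame(
            z, index=pd.Index(ids, name="individual_id"), columns=[f"z{k + 1}" for k in range(config.n_latent)]
        ),
        instability=pd.Series(s, index=pd.Index(ids, name="individual_id"), name="instability"),
        baseline=pd.Series(baseline, index=pd.Index(ids, name="individual_id"), name="baseline"),
        sex=pd.Series(sex, index=pd.Index(ids, name="individual_id"), name="sex"),
        beta_female=config.beta_female,
        beta_male=config.beta_male,
        pathologies={
            "measurement_error": dict(config.sigma_session_override),
            "DA": dict(config.da_shift),
            "antisymmetry": dict(config.antisymmetry_mode),
            "size_dependence": dict(config.size_dependence),
            "low_presence": dict(config.trait_presence),
        },
        covariates_complete=cov_complete,
    )
    return SyntheticCohort(
        measurements=measurements, covariates=covariates, schema=config.schema(), truth=truth
    )


def align_dimensions(coords: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    """Match fitted dimensions to true latent factors and fix their signs.

    The decomposition orders dimensions by explained variance and fixes
    signs by an internal convention, neither of which needs to coincide
    with the generator's factor indexing.  Dimensions are greedily
    matched to latent factors by largest absolute correlation and
    flipped so the matched correlation is positive; the returned frame
    has one column per true factor (``z1``..), making sign assertions on
    recovered effects well defined.
    """
    common = coords.index.intersection(truth.latent.index)
    C = np.corrcoef(
        truth.latent.loc[common].to_numpy().T, coords.loc[common].to_numpy().T
    )[: truth.latent.shape[1], truth.latent.shape[1]:]
    n_factors, n_dims = C.shape
    out = {}
    used: set[int] = set()
    order = np.argsort(-np.abs(C), axis=None)
    assigned: dict[int, int] = {}
    for flat in order:
        f, dim = divmod(flat, n_dims)
        if f in assigned or dim in used:
            continue
        assigned[f] = dim
        used.add(dim)
        if len(assigned) == min(n_factors, n_dims):
            break
    for f, dim in sorted(assigned.items()):
        sign = 1.0 if C[f, dim] >= 0 else -1.0
        out[f"z{f + 1}"] = sign * coords.iloc[:, dim]
    return pd.DataFrame(out, index=coords.index)
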