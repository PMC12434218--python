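"""Synthetic paediatric transplant cohorts for exercising the pipeline.

No patient-level data accompany the scoring index, so this module fabricates
cohorts with two ingredients:

* baseline covariates drawn from the published cohort mixture (83.2%
  allogeneic, 12.2% CAR-T, 4.6% gene therapy; 65.6% male; and so on), and
* day-by-day support-level trajectories from a covariate-stratified
  discrete-time Markov chain over the six states
  NONE..BESPOKE_PN, compressed into intervention episodes.

The shipped default transition model is phenomenological: each stratum's
chain starts at a high support level and de-escalates stepwise with
geometric sojourn times, scaled by a severity multiplier for malignant
disease, total body irradiation and cord-blood grafts.  Its constants were
hand-calibrated (by simulation, not fitted to data) so stratum score
medians land near the published subgroup medians -- allogeneic ~326,
CAR-T ~53, gene therapy ~124.5, malignant ~444, TBI ~476 -- and the cohort
median near 294.  Treat it as a plausible emulation, not a model of any
real service.

Reproducibility: each patient draws from an independent substream derived
from ``(seed, patient_index)``, so cohorts are stable under changes of
``n_patients`` and identical for identical configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .scoring import (
    DEFAULT_WINDOW,
    InterventionEpisode,
    PatientRecord,
    ScoreWindow,
    SupportLevel,
    ValidationError,
    WeightScheme,
    compute_patient_auc,
)

__all__ = [
    "CovariateProfile",
    "StratumChain",
    "TransitionModel",
    "CohortConfig",
    "LogisticOutcomeSpec",
    "DEFAULT_LOGISTIC_SPEC",
    "default_transition_model",
    "stratum_key",
    "sample_covariates",
    "sample_trajectory",
    "generate_cohort",
    "attach_logistic_outcomes",
    "covariate_dummy",
]

TRANSPLANT_TYPES = ("allogeneic", "car_t", "gene_therapy")
AGE_GROUPS = ("under2", "two_to_twelve", "over12")
_STATES = tuple(sorted(SupportLevel))  # rank order NONE..BESPOKE_PN


@dataclass(frozen=True)
class CovariateProfile:
    """Baseline characteristics of one patient.

    ``disease``, ``cell_source`` and ``tbi`` describe the allogeneic
    conditioning pathway and are present iff the transplant is allogeneic.
    """

    transplant_type: str
    age_group: str
    gender: str
    disease: str | None = None  # malignant | nonmalignant
    cell_source: str | None = None  # cord_blood | other
    tbi: bool | None = None

    def __post_init__(self) -> None:
        if self.transplant_type not in TRANSPLANT_TYPES:
            raise ValidationError(f"unknown transplant_type {self.transplant_type!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age_group {self.age_group!r}")
        if self.gender not in ("male", "female"):
            raise ValidationError(f"unknown gender {self.gender!r}")
        allo = self.transplant_type == "allogeneic"
        allo_fields = (self.disease, self.cell_source, self.tbi)
        if allo and any(v is None for v in allo_fields):
            raise ValidationError(
                "allogeneic profiles need disease, cell_source and tbi"
            )
        if not allo and any(v is not None for v in allo_fields):
            raise ValidationError(
                f"{self.transplant_type} profiles must not carry "
                "disease/cell_source/tbi"
            )
        if allo and self.disease not in ("malignant", "nonmalignant"):
            raise ValidationError(f"unknown disease {self.disease!r}")
        if allo and self.cell_source not in ("cord_blood", "other"):
            raise ValidationError(f"unknown cell_source {self.cell_source!r}")


@dataclass
class StratumChain:
    """Initial distribution and transition matrix for one covariate stratum."""

    initial: np.ndarray  # shape (6,)
    matrix: np.ndarray  # shape (6, 6), row-stochastic

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.initial.shape != (6,) or self.matrix.shape != (6, 6):
            raise ValidationError("chain needs initial (6,) and matrix (6,6)")
        if np.any(self.initial < 0) or np.any(self.matrix < 0):
            raise ValidationError("probabilities must be non-negative")
        if abs(self.initial.sum() - 1.0) > 1e-12:
            raise ValidationError("initial distribution must sum to 1")
        rowsums = self.matrix.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            raise ValidationError("every transition row must sum to 1")


@dataclass
class TransitionModel:
    """Per-stratum chains keyed by covariate stratum.

    Allogeneic strata are keyed
    ``allogeneic|<disease>|<tbi|no_tbi>|<cell_source>``; other modalities
    by transplant type alone.  A profile whose key is absent falls back to
    ``default_stratum`` with a warning.
    """

    chains: dict[str, StratumChain]
    default_stratum: str

    def __post_init__(self) -> None:
        if self.default_stratum not in self.chains:
            raise ValidationError(
                f"default stratum {self.default_stratum!r} not among chains"
            )

    def chain_for(self, profile: CovariateProfile) -> StratumChain:
        key = stratum_key(profile)
        chain = self.chains.get(key)
        if chain is None:
            warnings.warn(
                f"no transition chain for stratum {key!r}; falling back to "
                f"{self.default_stratum!r}",
                stacklevel=2,
            )
            chain = self.chains[self.default_stratum]
        return chain

    def to_json(self) -> str:
        payload = {
            "states": [s.token for s in _STATES],
            "default_stratum": self.default_stratum,
            "strata": {
                key: {
                    "initial": chain.initial.tolist(),
                    "matrix": chain.matrix.tolist(),
                }
                for key, chain in self.chains.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TransitionModel":
        payload = json.loads(text)
        expected = [s.token for s in _STATES]
        if payload.get("states") != expected:
            raise ValidationError(f"model states must be {expected}")
        chains = {
            key: StratumChain(
                initial=np.array(spec["initial"]),
                matrix=np.array(spec["matrix"]),
            )
            for key, spec in payload["strata"].items()
        }
        return cls(chains=chains, default_stratum=payload["default_stratum"])


def stratum_key(profile: CovariateProfile) -> str:
    if profile.transplant_type != "allogeneic":
        return profile.transplant_type
    tbi = "tbi" if profile.tbi else "no_tbi"
    return f"allogeneic|{profile.disease}|{tbi}|{profile.cell_source}"


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, covariate mixture and simulation switches.

    Mixture defaults are the published cohort composition (n = 131 overall;
    allogeneic-only covariates conditional on the n = 109 allogeneic subset).
    """

    n_patients: int = 131
    seed: int = 0
    p_allogeneic: float = 0.832
    p_car_t: float = 0.122
    p_gene_therapy: float = 0.046
    p_malignant: float = 0.413
    p_cord_blood: float = 0.284
    p_tbi: float = 0.128
    p_male: float = 0.656
    p_under2: float = 0.206
    p_two_to_twelve: float = 0.580
    p_over12: float = 0.214
    window: ScoreWindow = DEFAULT_WINDOW
    outcome_mode: str = "trajectory"  # trajectory | logistic
    death_hazard: float = 0.0  # per-day hazard; 0 disables synthetic deaths

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if self.outcome_mode not in ("trajectory", "logistic"):
            raise ValidationError(f"unknown outcome_mode {self.outcome_mode!r}")
        triples = {
            "transplant mixture": (self.p_allogeneic, self.p_car_t, self.p_gene_therapy),
            "age mixture": (self.p_under2, self.p_two_to_twelve, self.p_over12),
        }
        for name, probs in triples.items():
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValidationError(f"{name}: proportions must lie in [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1 (got {sum(probs)})")
        for name, p in (
            ("p_malignant", self.p_malignant),
            ("p_cord_blood", self.p_cord_blood),
            ("p_tbi", self.p_tbi),
            ("p_male", self.p_male),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.death_hazard < 1.0:
            raise ValidationError("death_hazard must lie in [0, 1)")


@dataclass(frozen=True)
class LogisticOutcomeSpec:
    """Ground-truth logistic model used to simulate Day +100 >=PN outcomes.

    ``coefficients`` are keyed by dummy-term name (``male``, ``under2``,
    ``over12``, ``nonmalignant``, ``other_source``, ``tbi``); the score
    enters per unit through ``auc_coefficient``.
    """

    intercept: float = 0.0
    auc_coefficient: float = 0.009
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = [self.intercept, self.auc_coefficient, *self.coefficients.values()]
        if not all(np.isfinite(values)):
            raise ValidationError("logistic outcome coefficients must be finite")


#: Default ground truth mirroring the published multivariable estimates.
DEFAULT_LOGISTIC_SPEC = LogisticOutcomeSpec(
    intercept=0.561,
    auc_coefficient=0.009,
    coefficients={
        "male": -0.494,
        "under2": -1.200,
        "over12": -0.866,
        "nonmalignant": -2.091,
        "other_source": -0.524,
        "tbi": -2.028,
    },
)


def covariate_dummy(profile: CovariateProfile, term: str) -> float:
    """Reference-coded dummy value for one predictor term.

    References: female, age 2-12, malignant disease, cord-blood source, no
    TBI.  Allogeneic-only terms evaluate to 0 for other modalities.
    """
    if term == "male":
        return float(profile.gender == "male")
    if term == "under2":
        return float(profile.age_group == "under2")
    if term == "over12":
        return float(profile.age_group == "over12")
    if term == "nonmalignant":
        return float(profile.disease == "nonmalignant")
    if term == "other_source":
        return float(profile.cell_source == "other")
    if term == "tbi":
        return float(bool(profile.tbi))
    raise ValidationError(f"unknown predictor term {term!r}")


# --- default transition model -------------------------------------------------
#
# Stepwise de-escalation chains: a patient starts on parenteral (or bespoke
# parenteral) support, steps down one level at a time with geometric sojourn
# times, and leaves dietetic follow-up from routine review.  Severity
# multipliers stretch the sojourns on the invasive levels (enteral and
# above).  Constants below are the frozen hand-calibration.

_ALLO_BASE_SOJOURN = {  # mean days at each level, base severity
    SupportLevel.BESPOKE_PN: 9.0,
    SupportLevel.PN: 20.0,
    SupportLevel.ENTERAL: 15.0,
    SupportLevel.ORAL: 11.0,
    SupportLevel.ROUTINE: 26.0,
}
_MALIGNANT_MULT = 1.90
_TBI_MULT = 1.90
_CORD_MULT = 1.20
_BESPOKE_START_BASE = 0.12  # P(start at bespoke PN), scaled by severity
_ALLO_RELAPSE = 0.006  # daily P(re-escalate to PN) below PN, allogeneic
_LIGHT_RELAPSE = 0.002  # lighter-conditioning modalities
_RECONTACT = 0.004  # daily P(NONE -> routine review)


def _stepdown_chain(
    sojourn: Mapping[SupportLevel, float],
    initial: Mapping[SupportLevel, float],
    relapse: float = 0.0,
    recontact: float = 0.0,
) -> StratumChain:
    """Chain that mostly de-escalates one level per transition.

    ``relapse`` is a small daily probability of re-escalating to PN from
    any sub-PN support level (complications re-opening parenteral need);
    ``recontact`` the probability of re-entering routine review from NONE.
    """
    matrix = np.zeros((6, 6))
    matrix[0, 0] = 1.0 - recontact
    matrix[0, SupportLevel.ROUTINE] = recontact
    for level in _STATES[1:]:
        down = 1.0 / max(sojourn.get(level, 1.0), 1.0)
        up = relapse if level < SupportLevel.PN else 0.0
        matrix[level, level - 1] = down
        matrix[level, SupportLevel.PN] += up
        matrix[level, level] = 1.0 - down - up
    init = np.zeros(6)
    for level, p in initial.items():
        init[level] = p
    init[SupportLevel.NONE] += 1.0 - init.sum()  # remainder: no contact
    return StratumChain(initial=init, matrix=matrix)


def _allo_chain(disease: str, tbi: bool, cell_source: str) -> StratumChain:
    severity = 1.0
    if disease == "malignant":
        severity *= _MALIGNANT_MULT
    if tbi:
        severity *= _TBI_MULT
    if cell_source == "cord_blood":
        severity *= _CORD_MULT
    sojourn = dict(_ALLO_BASE_SOJOURN)
    for level in (SupportLevel.BESPOKE_PN, SupportLevel.PN, SupportLevel.ENTERAL):
        sojourn[level] *= severity
    p_bespoke = min(0.75, _BESPOKE_START_BASE * severity)
    return _stepdown_chain(
        sojourn,
        {SupportLevel.BESPOKE_PN: p_bespoke, SupportLevel.PN: 1.0 - p_bespoke},
        relapse=_ALLO_RELAPSE,
        recontact=_RECONTACT,
    )


def default_transition_model() -> TransitionModel:
    """The shipped hand-calibrated default (see module docstring)."""
    chains: dict[str, StratumChain] = {}
    for disease in ("malignant", "nonmalignant"):
        for tbi in (True, False):
            for source in ("cord_blood", "other"):
                profile_key = (
                    f"allogeneic|{disease}|{'tbi' if tbi else 'no_tbi'}|{source}"
                )
                chains[profile_key] = _allo_chain(disease, tbi, source)
    chains["car_t"] = _stepdown_chain(
        {
            SupportLevel.ENTERAL: 10.0,
            SupportLevel.ORAL: 13.0,
            SupportLevel.ROUTINE: 48.0,
        },
        {
            SupportLevel.ENTERAL: 0.18,
            SupportLevel.ORAL: 0.45,
            SupportLevel.ROUTINE: 0.32,
        },
        relapse=_LIGHT_RELAPSE,
        recontact=_RECONTACT,
    )
    chains["gene_therapy"] = _stepdown_chain(
        {
            SupportLevel.PN: 15.0,
            SupportLevel.ENTERAL: 23.0,
            SupportLevel.ORAL: 17.0,
            SupportLevel.ROUTINE: 55.0,
        },
        {
            SupportLevel.PN: 0.15,
            SupportLevel.ENTERAL: 0.55,
            SupportLevel.ORAL: 0.30,
        },
        relapse=_LIGHT_RELAPSE,
        recontact=_RECONTACT,
    )
    return TransitionModel(
        chains=chains, default_stratum="allogeneic|nonmalignant|no_tbi|other"
    )


# --- sampling -----------------------------------------------------------------


def sample_covariates(config: CohortConfig, rng: np.random.Generator) -> CovariateProfile:
    """Draw one covariate profile from the configured mixture.

    Covariates are sampled independently; allogeneic-only fields are drawn
    only when the transplant-type draw lands on allogeneic.
    """
    tt = rng.choice(
        TRANSPLANT_TYPES,
        p=(config.p_allogeneic, config.p_car_t, config.p_gene_therapy),
    )
    age = rng.choice(
        AGE_GROUPS, p=(config.p_under2, config.p_two_to_twelve, config.p_over12)
    )
    gender = "male" if rng.random() < config.p_male else "female"
    if tt != "allogeneic":
        return CovariateProfile(transplant_type=tt, age_group=age, gender=gender)
    return CovariateProfile(
        transplant_type="allogeneic",
        age_group=age,
        gender=gender,
        disease="malignant" if rng.random() < config.p_malignant else "nonmalignant",
        cell_source="cord_blood" if rng.random() < config.p_cord_blood else "other",
        tbi=bool(rng.random() < config.p_tbi),
    )


def sample_trajectory(
    profile: CovariateProfile,
    model: TransitionModel,
    window: ScoreWindow = DEFAULT_WINDOW,
    rng: np.random.Generator | None = None,
    patient_id: str = "synthetic",
) -> list[InterventionEpisode]:
    """Simulate one support-level trajectory and compress it into episodes.

    One chain step per window day, starting from the stratum's initial
    distribution on the first day; maximal runs of each non-NONE state
    become episodes.
    """
    if rng is None:
        rng = np.random.default_rng()
    chain = model.chain_for(profile)
    cum_init = np.cumsum(chain.initial)
    cum_rows = np.cumsum(chain.matrix, axis=1)
    u = rng.random(window.length)
    states = np.empty(window.length, dtype=np.int64)
    states[0] = np.searchsorted(cum_init, u[0], side="right")
    for d in range(1, window.length):
        states[d] = np.searchsorted(cum_rows[states[d - 1]], u[d], side="right")
    # clip guards against u landing on the far edge of rounded cumsums
    np.clip(states, 0, 5, out=states)

    episodes: list[InterventionEpisode] = []
    run_start = 0
    for d in range(1, window.length + 1):
        if d == window.length or states[d] != states[run_start]:
            level = SupportLevel(int(states[run_start]))
            if level is not SupportLevel.NONE:
                episodes.append(
                    InterventionEpisode(
                        patient_id=patient_id,
                        level=level,
                        start_day=window.first_day + run_start,
                        end_day=window.first_day + d - 1,
                    )
                )
            run_start = d
    return episodes


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def generate_cohort(
    config: CohortConfig, model: TransitionModel | None = None
) -> list[PatientRecord]:
    """Generate ``config.n_patients`` synthetic patient records.

    Deterministic for a fixed config: patient ``i`` consumes only the
    substream seeded by ``(config.seed, i)``.  Follow-up covers the whole
    window unless a positive ``death_hazard`` truncates it (used to test
    the censoring filter; off by default).
    """
    if model is None:
        model = default_transition_model()
    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i + 1:04d}"
        profile = sample_covariates(config, rng)
        episodes = sample_trajectory(
            profile, model, config.window, rng, patient_id=pid
        )
        followup = config.window.last_day + 1
        died = False
        if config.death_hazard > 0.0:
            death_day = int(rng.geometric(config.death_hazard))
            if death_day <= config.window.last_day:
                followup = death_day
                died = True
                episodes = [
                    ep if ep.end_day < death_day else replace(ep, end_day=death_day - 1)
                    for ep in episodes
                    if ep.start_day < death_day
                ]
        records.append(
            PatientRecord(
                patient_id=pid,
                episodes=episodes,
                covariates=profile,
                followup_days=followup,
                died_before_day100=died,
            )
        )
    return records


def attach_logistic_outcomes(
    records: Sequence[PatientRecord],
    spec: LogisticOutcomeSpec = DEFAULT_LOGISTIC_SPEC,
    weights: WeightScheme | None = None,
    window: ScoreWindow = DEFAULT_WINDOW,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate Bernoulli Day +100 >=PN outcomes from a known logistic model.

    outcome_i ~ Bernoulli(logit^-1(b0 + sum_k b_k x_ik + b_auc * auc_i)),
    with auc_i the additive-mode score over ``window``.  The draw is stored
    on each record as ``pn_day100_override`` (replacing the trajectory-
    derived endpoint) and returned as a boolean array.  Used as the ground
    truth in parameter-recovery simulations.
    """
    if rng is None:
        rng = np.random.default_rng()
    if weights is None:
        weights = WeightScheme()
    eta = np.empty(len(records))
    for i, rec in enumerate(records):
        auc = compute_patient_auc(rec, weights, window, "additive").auc
        lin = spec.intercept + spec.auc_coefficient * auc
        for term, beta in spec.coefficients.items():
            lin += beta * covariate_dummy(rec.covariates, term)
        eta[i] = lin
    outcomes = rng.random(len(records)) < expit(eta)
    for rec, y in zip(records, outcomes):
        rec.pn_day100_override = bool(y)
    return outcomes
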