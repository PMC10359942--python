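"""Cohort simulation configuration.

The defaults encode the study conditions of a glucose-depletion live-imaging
experiment in hTERT-RPE1 cells: 15-min sampling over 48 h, per-condition
cell-cycle phase-duration distributions, a quiescent CDK2 (Cyt/Nuc) baseline
of ~0.6, and mother-stage-dependent daughter fate mixtures (86.54% quiescence
for mothers caught in G1 at treatment onset, 51.22% for mothers caught in S;
7.14% under control conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import optimize, stats

CONDITIONS = ("control", "glucose_depletion", "p21_degradation")

PHASES = ("G1", "S", "G2", "M")

#: Reference phase-duration moments (mean, SD) in hours, per condition.
#: p21_degradation cells cycle with depletion kinetics until p21 is degraded.
PHASE_DURATIONS = {
    "control": {
        "G1": (4.92, 2.09),
        "S": (5.59, 1.52),
        "G2": (2.19, 0.93),
        "M": (0.81, 0.13),
    },
    "glucose_depletion": {
        "G1": (7.39, 4.38),
        "S": (6.23, 2.05),
        "G2": (3.74, 1.42),
        "M": (0.84, 0.23),
    },
}
PHASE_DURATIONS["p21_degradation"] = PHASE_DURATIONS["glucose_depletion"]

#: Probability that a daughter enters quiescence, conditional on the mother's
#: cell-cycle stage at treatment onset.
FATE_PROBS = {
    "control": {"G1": 0.0714, "S": 0.0714},
    "glucose_depletion": {"G1": 0.8654, "S": 0.5122},
}
FATE_PROBS["p21_degradation"] = FATE_PROBS["glucose_depletion"]

#: Default multiplicative log-normal measurement-noise sigma per channel.
MEASUREMENT_NOISE = {
    "Cdt1": 0.10,
    "Geminin": 0.10,
    "SLBP": 0.10,
    "H1": 0.05,
    "cdk2_nuc": 0.03,
    "cdk2_cyt": 0.03,
    "p21": 0.05,
}

#: Fraction of captured mothers that are in G1 (vs S) at treatment onset.
#: Chosen as the unique mixture weight under which the stage-conditional
#: quiescence probabilities (86.54% / 51.22%) reproduce the observed marginal
#: quiescent fraction of 64.93%: w = (0.6493 - 0.5122) / (0.8654 - 0.5122).
DEFAULT_P_STAGE_G1 = (0.6493 - 0.5122) / (0.8654 - 0.5122)


@dataclass
class P21Params:
    """Parameters of p21 reporter dynamics and inheritance.

    The G1 group (mothers in G1 at treatment onset) accumulates p21 in the
    mother — a modest rise in G1, suppression in S, and a robust rise over
    G2/M to a per-cell plateau ``L`` — which is then split between the two
    daughters with near-equal conserved fractions f = (1 +/- delta)/2.
    The S group starts daughters near zero and accumulates de novo at an
    independent per-daughter rate.

    ``mother_level_mean``/``mother_level_cv`` parameterize the log-normal
    population distribution of L (a.u.).  ``split_sd`` is the SD of delta;
    its default was solved in closed form so that the pooled sibling
    discrepancy D over 5-h post-mitosis window series (including per-frame
    measurement noise) is 0.10, i.e. 1 - D = 0.90.  ``rise_shape_sd`` is the
    log-SD of the per-cell curvature exponent of the mother's G2/M ramp; it
    sets how strongly the mother's 5-h pre-mitosis window mean decouples from
    the inherited plateau and was fixed so the predicted mother-daughter
    window-mean Pearson correlation is 0.79.
    """

    mother_level_mean: float = 100.0
    mother_level_cv: float = 0.5
    split_sd: float = 0.0626
    rise_shape_sd: float = 0.55
    g1_rise_frac: float = 0.15
    s_floor_frac: float = 0.05
    denovo_rate_median: float = 4.0
    denovo_rate_cv: float = 0.6
    baseline: float = 2.0
    #: p21_degradation scenario: hours (absolute time) at which induced
    #: degradation starts; reporter decays to undetectable within ~2 h.
    iaa_time: Optional[float] = None


@dataclass
class CDK2Params:
    """CDK2 sensor Cyt/Nuc ratio trace parameters."""

    quiescent_baseline: float = 0.6
    mitotic_peak: float = 2.0
    nuclear_level: float = 50.0


@dataclass
class SimConfig:
    """Full parameterization of a synthetic lineage-linked reporter cohort."""

    condition: str = "control"
    sampling_interval: float = 0.25
    horizon: float = 48.0
    n_mothers: int = 100
    phase_duration_params: dict = field(default_factory=dict)
    fate_probs: dict = field(default_factory=dict)
    p_stage_g1: float = DEFAULT_P_STAGE_G1
    quiescent_baseline: float = 0.6
    p21_params: P21Params = field(default_factory=P21Params)
    cdk2_params: CDK2Params = field(default_factory=CDK2Params)
    measurement_noise: dict = field(default_factory=dict)
    #: per-cell brightness (log-normal CV) shared by all Fucci channels
    brightness_cv: float = 0.15
    #: minimum phase duration (truncation point of the duration distributions)
    min_phase_duration: float = 0.25
    rng_seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not self.phase_duration_params:
            self.phase_duration_params = {
                k: tuple(v) for k, v in PHASE_DURATIONS[self.condition].items()
            }
        if not self.fate_probs:
            self.fate_probs = dict(FATE_PROBS[self.condition])
        noise = dict(MEASUREMENT_NOISE)
        noise.update(self.measurement_noise)
        self.measurement_noise = noise
        self.cdk2_params.quiescent_baseline = self.quiescent_baseline
        self.validate()

    def validate(self):
        if self.n_mothers <= 0:
            raise ValueError("n_mothers must be a positive integer")
        if self.sampling_interval <= 0 or self.horizon <= 0:
            raise ValueError("sampling_interval and horizon must be positive")
        n = self.horizon / self.sampling_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_interval must divide horizon")
        for phase in PHASES:
            mean, sd = self.phase_duration_params[phase]
            if mean <= 0 or sd <= 0:
                raise ValueError(f"phase {phase}: mean and SD must be positive")
        for stage, p in self.fate_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fate probability for {stage} outside [0, 1]")
        if not 0.0 <= self.p_stage_g1 <= 1.0:
            raise ValueError("p_stage_g1 outside [0, 1]")
        for ch, sigma in self.measurement_noise.items():
            if sigma < 0:
                raise ValueError(f"negative noise sigma for channel {ch}")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_duration_params"] = {
            k: list(v) for k, v in self.phase_duration_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "p21_params" in d and isinstance(d["p21_params"], dict):
            d["p21_params"] = P21Params(**d["p21_params"])
        if "cdk2_params" in d and isinstance(d["cdk2_params"], dict):
            d["cdk2_params"] = CDK2Params(**d["cdk2_params"])
        if "phase_duration_params" in d:
            d["phase_duration_params"] = {
                k: tuple(v) for k, v in d["phase_duration_params"].items()
            }
        return cls(**d)


def truncnorm_for_mean(target_mean: float, sd: float, lower: float) -> stats.rv_frozen:
    """Truncated normal (at ``lower``) whose *truncated* mean equals ``target_mean``.

    Truncating a normal at a lower bound shifts its mean upward; naively using
    the target moments as the parent parameters would therefore bias every
    sampled duration high (by ~0.5 h for broad distributions).  The location
    is solved so the realized mean matches the target; the scale is kept at
    the target SD.
    """
    if target_mean <= lower:
        raise ValueError("target mean must exceed the truncation point")

    def realized_mean(loc):
        a = (lower - loc) / sd
        return stats.truncnorm(a, np.inf, loc=loc, scale=sd).mean() - target_mean

    # realized mean is increasing in loc and always > max(loc, lower)
    lo = target_mean - 6 * sd
    hi = target_mean
    loc = optimize.brentq(realized_mean, lo, hi, xtol=1e-10)
    a = (lower - loc) / sd
    return stats.truncnorm(a, np.inf, loc=loc, scale=sd)


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a log-normal with the given mean and CV."""
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)
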