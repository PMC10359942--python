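"""Seeded synthetic cohorts of lineage-linked reporter trajectories.

Every mother cell is captured mid-cycle at t = 0 (treatment onset), completes
its current cycle with condition-dependent phase durations, and divides into
two daughters whose proliferation/quiescence fate follows the configured
mother-stage-dependent mixture.  Reporter waveforms (Fucci4 channels, CDK2
sensor nucleus/cytoplasm signals, p21) are piecewise analytic shapes with
known ground-truth phase boundaries, so every downstream caller can be
validated against simulator truth.

Fate is not drawn as a bare coin flip: it is realised by thresholding the
p21 quantity that drives the decision — the inherited mother p21 level in the
G1 group, the de-novo accumulation rate in the S group and under control —
with thresholds solved so the marginal quiescence probability per group
equals the configured ``fate_probs``.  Shared inheritance therefore forces
sibling concordance as the split noise vanishes, while de-novo accumulation
makes sibling fates independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .config import (
    PHASES,
    P21Params,
    SimConfig,
    lognormal_params,
    truncnorm_for_mean,
)

FUCCI_CHANNELS = ("Cdt1", "Geminin", "SLBP", "H1")
ALL_CHANNELS = FUCCI_CHANNELS + ("cdk2_nuc", "cdk2_cyt", "p21")


@dataclass
class ReporterTrack:
    """One cell's sampled multi-channel reporter time series."""

    cell_id: str
    parent_id: Optional[str]
    birth_time: float
    end_time: float
    times: np.ndarray
    channels: dict
    #: simulator-only ground truth (phase boundaries, fate, ...)
    truth: dict = field(default_factory=dict)

    @property
    def division_time(self) -> Optional[float]:
        return self.truth.get("division_time")

    def __post_init__(self):
        dt = np.diff(self.times)
        if len(dt) and (dt <= 0).any():
            raise ValueError(f"{self.cell_id}: times must be strictly increasing")
        for name, vals in self.channels.items():
            if len(vals) != len(self.times):
                raise ValueError(f"{self.cell_id}: channel {name} length mismatch")


@dataclass
class Cohort:
    tracks: list
    lineage: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig
    truncation_warning: bool = False

    def track(self, cell_id: str) -> ReporterTrack:
        return self._index()[cell_id]

    def _index(self):
        if not hasattr(self, "_by_id"):
            self._by_id = {t.cell_id: t for t in self.tracks}
        return self._by_id

    @property
    def mothers(self):
        return [t for t in self.tracks if t.parent_id is None]

    @property
    def daughters(self):
        return [t for t in self.tracks if t.parent_id is not None]


# ---------------------------------------------------------------------------
# fate thresholds


def _g1_inheritance_threshold(p21: P21Params, p_quiescent: float) -> float:
    """p21 level above which a G1-group daughter commits to quiescence.

    The inherited level is (L/2)(1 + delta) with L log-normal and delta
    normal; the threshold is solved so the marginal exceedance probability
    equals ``p_quiescent``.
    """
    if p_quiescent <= 0.0:
        return np.inf
    if p_quiescent >= 1.0:
        return 0.0
    mu, sig = lognormal_params(p21.mother_level_mean, p21.mother_level_cv)
    ln = stats.lognorm(s=sig, scale=np.exp(mu))
    sd = p21.split_sd

    def exceed(theta):
        if sd == 0:
            return ln.sf(2.0 * theta)

        def integrand(d):
            return stats.norm.pdf(d, scale=sd) * ln.sf(2.0 * theta / (1.0 + d))

        lo, hi = max(-0.95, -8 * sd), 8 * sd
        val, _ = integrate.quad(integrand, lo, hi, limit=200)
        return val

    lo, hi = 1e-6, p21.mother_level_mean * 50
    return optimize.brentq(lambda th: exceed(th) - p_quiescent, lo, hi, xtol=1e-9)


def _denovo_rate_threshold(p21: P21Params, p_quiescent: float) -> float:
    """De-novo accumulation rate above which a daughter commits to quiescence."""
    if p_quiescent <= 0.0:
        return np.inf
    if p_quiescent >= 1.0:
        return 0.0
    sigma = np.sqrt(np.log(1.0 + p21.denovo_rate_cv**2))
    return float(
        stats.lognorm(s=sigma, scale=p21.denovo_rate_median).ppf(1.0 - p_quiescent)
    )


# ---------------------------------------------------------------------------
# waveforms


def _fucci_waveforms(t_rel, boundaries, amp):
    """Piecewise-linear Fucci4 shapes over one complete cycle.

    ``boundaries`` = (b1, b2, b3, b4): cumulative G1/S, S/G2, G2/M and
    division times relative to birth.  Peaks used for boundary detection are
    locally symmetric (equal rise/fall slopes) so that smoothing and
    symmetric measurement noise do not bias their detected location.
    """
    b1, b2, b3, b4 = boundaries
    d_g1 = b1
    out = {}

    # Cdt1: rises through G1 to its apex at the G1/S boundary, then decays
    # in S at the same slope until reaching a low floor.
    slope = 0.90 / d_g1
    rise = 0.10 + slope * t_rel
    fall = 1.0 - slope * (t_rel - b1)
    cdt1 = np.where(t_rel < b1, rise, np.maximum(fall, 0.05))
    out["Cdt1"] = amp * cdt1

    # Geminin: low in G1, rises S -> G2/M boundary, collapses during M.
    gem = np.full_like(t_rel, 0.02)
    rising = (t_rel >= b1) & (t_rel < b3)
    gem = np.where(rising, 0.02 + 0.98 * (t_rel - b1) / (b3 - b1), gem)
    in_m = t_rel >= b3
    gem = np.where(in_m, np.maximum(1.0 - 0.98 * (t_rel - b3) / (b4 - b3), 0.02), gem)
    out["Geminin"] = amp * gem

    # SLBP: symmetric triangular peak at the S/G2 boundary.
    half = 0.9 * min(b2 - b1, b3 - b2)
    half = max(half, 0.5)
    slbp = np.maximum(0.15, 1.0 - 0.85 * np.abs(t_rel - b2) / half)
    out["SLBP"] = amp * slbp

    # H1: constant, with a step-up mitotic signature during M (chromatin
    # condensation).
    out["H1"] = amp * np.where(t_rel >= b3, 1.8, 1.0)
    return out


def _quiescent_waveforms(t_rel, amp):
    """Fucci shapes of a quiescent (G0) daughter: slow sub-peak Cdt1 rise,
    silent Geminin/SLBP, constant H1."""
    cdt1 = 0.10 + 0.45 * np.minimum(t_rel / 10.0, 1.0)
    return {
        "Cdt1": amp * cdt1,
        "Geminin": amp * np.full_like(t_rel, 0.02),
        "SLBP": amp * np.full_like(t_rel, 0.15),
        "H1": amp * np.ones_like(t_rel),
    }


def _mother_p21(t_rel, boundaries, level, kappa, p21: P21Params):
    """G1-group mother p21: modest G1 rise, S suppression, robust G2/M ramp
    with per-cell curvature ``kappa`` ending at the plateau ``level``."""
    b1, b2, b3, b4 = boundaries
    g1_top = p21.g1_rise_frac * level
    floor = p21.s_floor_frac * level
    vals = np.empty_like(t_rel)
    in_g1 = t_rel < b1
    vals[in_g1] = p21.baseline + (g1_top - p21.baseline) * t_rel[in_g1] / b1
    decay_end = b1 + 0.5 * (b2 - b1)
    in_decay = (t_rel >= b1) & (t_rel < decay_end)
    vals[in_decay] = g1_top + (floor - g1_top) * (t_rel[in_decay] - b1) / (
        decay_end - b1
    )
    in_flat = (t_rel >= decay_end) & (t_rel < b2)
    vals[in_flat] = floor
    in_ramp = t_rel >= b2
    frac = np.clip((t_rel[in_ramp] - b2) / (b4 - b2), 0.0, 1.0)
    vals[in_ramp] = floor + (level - floor) * frac**kappa
    return vals


# ---------------------------------------------------------------------------
# cohort assembly


def _snap(x, dt):
    return np.round(x / dt) * dt


def _draw_durations(rng, dists, dt):
    """Per-phase durations snapped to the sampling grid (>= one frame each)."""
    durs = {}
    for phase in PHASES:
        d = dists[phase].rvs(random_state=rng)
        durs[phase] = max(_snap(d, dt), dt)
    return durs


def _apply_noise(values, sigma, rng):
    """Multiplicative log-normal noise with unit mean."""
    if sigma <= 0:
        return values
    return values * rng.lognormal(-0.5 * sigma * sigma, sigma, size=len(values))


class _CellBuilder:
    """Shared machinery for building one cell's sampled track."""

    def __init__(self, config: SimConfig):
        self.cfg = config
        self.dt = config.sampling_interval

    def times(self, start, end):
        n = int(round((end - start) / self.dt))
        return start + self.dt * np.arange(n)

    def noisy(self, channels, rng):
        out = {}
        for name, vals in channels.items():
            sigma = self.cfg.measurement_noise.get(name, 0.0)
            out[name] = _apply_noise(np.asarray(vals, dtype=float), sigma, rng)
        return out


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a seeded cohort of mother + daughter reporter tracks.

    Returns a :class:`Cohort` holding the tracks, the lineage table (one row
    per daughter: cell_id, parent_id, division_time_h) and a per-cell ground
    truth table.  Identical config + seed gives a bit-identical cohort: each
    cell draws from its own seed substream, so enlarging ``n_mothers`` leaves
    existing cells unchanged.
    """
    cfg = config
    dt = cfg.sampling_interval
    p21p = cfg.p21_params
    cdk2p = cfg.cdk2_params
    builder = _CellBuilder(cfg)

    dists = {
        ph: truncnorm_for_mean(*cfg.phase_duration_params[ph], cfg.min_phase_duration)
        for ph in PHASES
    }
    mean_cycle = sum(cfg.phase_duration_params[ph][0] for ph in PHASES)
    truncation_warning = cfg.horizon < mean_cycle
    if truncation_warning:
        warnings.warn(
            "horizon shorter than one mean cell cycle; most cells will be truncated",
            stacklevel=2,
        )

    theta_g1 = _g1_inheritance_threshold(p21p, cfg.fate_probs["G1"])
    rate_thresholds = {
        stage: _denovo_rate_threshold(p21p, cfg.fate_probs[stage])
        for stage in ("G1", "S")
    }
    denovo_sigma = np.sqrt(np.log(1.0 + p21p.denovo_rate_cv**2))
    level_mu, level_sigma = lognormal_params(
        p21p.mother_level_mean, p21p.mother_level_cv
    )
    inherited_mechanism = cfg.condition in ("glucose_depletion", "p21_degradation")

    tracks, lineage_rows, truth_rows = [], [], []

    for i in range(cfg.n_mothers):
        m_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(i,))
        )
        mid = f"c{i:05d}"
        durs = _draw_durations(m_rng, dists, dt)
        b1 = durs["G1"]
        b2 = b1 + durs["S"]
        b3 = b2 + durs["G2"]
        b4 = b3 + durs["M"]

        # stage at treatment (t = 0) and elapsed cycle position
        stage = "G1" if m_rng.random() < cfg.p_stage_g1 else "S"
        if stage == "G1":
            elapsed = min(_snap(m_rng.uniform(0, b1), dt), b1 - dt)
        else:
            elapsed = b1 + min(_snap(m_rng.uniform(0, b2 - b1), dt), b2 - b1 - dt)
        elapsed = max(elapsed, 0.0)
        birth = -elapsed
        division = birth + b4

        # mother p21 machinery
        kappa = m_rng.lognormal(0.0, p21p.rise_shape_sd)
        if inherited_mechanism and stage == "G1":
            level = m_rng.lognormal(level_mu, level_sigma)
        else:
            level = None  # S-group / control mothers stay near baseline
        split_delta = (
            np.clip(m_rng.normal(0.0, p21p.split_sd), -0.45, 0.45)
            if p21p.split_sd > 0
            else 0.0
        )

        divided = division <= cfg.horizon
        t_m = builder.times(birth, division if divided else cfg.horizon + dt)
        t_rel = t_m - birth
        bright = m_rng.lognormal(0.0, cfg.brightness_cv) if cfg.brightness_cv else 1.0
        chans = _fucci_waveforms(t_rel, (b1, b2, b3, b4), 100.0 * bright)
        ratio = cdk2p.quiescent_baseline + (
            cdk2p.mitotic_peak - cdk2p.quiescent_baseline
        ) * (t_rel / b4)
        nuc = np.full_like(t_m, cdk2p.nuclear_level * bright)
        chans["cdk2_nuc"] = nuc
        chans["cdk2_cyt"] = ratio * nuc
        if level is not None:
            chans["p21"] = _mother_p21(t_rel, (b1, b2, b3, b4), level, kappa, p21p)
        else:
            chans["p21"] = np.full_like(t_m, p21p.baseline)
        chans = builder.noisy(chans, m_rng)

        m_truth = {
            "role": "mother",
            "stage_at_treatment": stage,
            "fate": "proliferative",
            "division_time": division if divided else np.nan,
            "t_G1S": birth + b1,
            "t_SG2": birth + b2,
            "t_G2M": birth + b3,
            "p21_level": level if level is not None else 0.0,
        }
        tracks.append(
            ReporterTrack(mid, None, birth, t_m[-1], t_m, chans, dict(m_truth))
        )
        truth_rows.append({"cell_id": mid, "parent_id": "", "birth_time": birth, **m_truth})

        # daughters -----------------------------------------------------
        if not divided:
            continue
        if inherited_mechanism and stage == "G1":
            inherited = [
                level / 2.0 * (1.0 + split_delta),
                level / 2.0 * (1.0 - split_delta),
            ]
        else:
            inherited = [p21p.baseline, p21p.baseline]

        for j in (0, 1):
            d_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(i, 1 + j))
            )
            did = f"{mid}d{j}"
            denovo_rate = d_rng.lognormal(
                np.log(p21p.denovo_rate_median), denovo_sigma
            )
            if inherited_mechanism and stage == "G1":
                quiescent = inherited[j] > theta_g1
            else:
                quiescent = denovo_rate > rate_thresholds[stage]

            d_bright = (
                d_rng.lognormal(0.0, cfg.brightness_cv) if cfg.brightness_cv else 1.0
            )
            d_truth = {
                "role": "daughter",
                "stage_at_treatment": stage,
                "fate": "quiescent" if quiescent else "proliferative",
                "p21_inherited": inherited[j],
            }

            if quiescent:
                t_d = builder.times(division, cfg.horizon + dt)
                rel = t_d - division
                chans = _quiescent_waveforms(rel, 100.0 * d_bright)
                nuc = np.full_like(t_d, cdk2p.nuclear_level * d_bright)
                chans["cdk2_nuc"] = nuc
                chans["cdk2_cyt"] = cdk2p.quiescent_baseline * nuc
                if inherited_mechanism and stage == "G1":
                    p21 = np.full_like(t_d, inherited[j])
                else:
                    p21 = inherited[j] + denovo_rate * rel
                chans["p21"] = p21
                d_truth["division_time"] = np.nan
            else:
                d_durs = _draw_durations(d_rng, dists, dt)
                db1 = d_durs["G1"]
                db2 = db1 + d_durs["S"]
                db3 = db2 + d_durs["G2"]
                db4 = db3 + d_durs["M"]
                d_div = division + db4
                end = min(d_div, cfg.horizon + dt)
                t_d = builder.times(division, end)
                rel = t_d - division
                chans = _fucci_waveforms(rel, (db1, db2, db3, db4), 100.0 * d_bright)
                ratio = cdk2p.quiescent_baseline + (
                    cdk2p.mitotic_peak - cdk2p.quiescent_baseline
                ) * (rel / db4)
                nuc = np.full_like(t_d, cdk2p.nuclear_level * d_bright)
                chans["cdk2_nuc"] = nuc
                chans["cdk2_cyt"] = ratio * nuc
                if inherited_mechanism and stage == "G1":
                    # inherited p21 decays as the cell re-enters the cycle
                    p21 = inherited[j] * np.exp(-rel / 12.0)
                else:
                    p21 = inherited[j] + 0.3 * denovo_rate * rel
                chans["p21"] = p21
                completed = d_div <= cfg.horizon
                d_truth["division_time"] = d_div if completed else np.nan
                if completed:
                    d_truth.update(
                        {
                            "t_G1S": division + db1,
                            "t_SG2": division + db2,
                            "t_G2M": division + db3,
                        }
                    )

            # p21_degradation scenario: induced collapse of the reporter,
            # CDK2 then rises but plateaus below the mitotic peak.
            if cfg.condition == "p21_degradation" and p21p.iaa_time is not None:
                after = t_d >= p21p.iaa_time
                decay = np.exp(-(t_d[after] - p21p.iaa_time) / 0.5)
                chans["p21"] = np.asarray(chans["p21"], dtype=float)
                chans["p21"][after] *= decay
                if quiescent:
                    rise = 1.0 - np.exp(-(t_d[after] - p21p.iaa_time) / 6.0)
                    plateau = 0.75 * cdk2p.mitotic_peak
                    r_new = cdk2p.quiescent_baseline + (
                        plateau - cdk2p.quiescent_baseline
                    ) * rise
                    chans["cdk2_cyt"][after] = r_new * chans["cdk2_nuc"][after]

            chans = builder.noisy(chans, d_rng)
            tracks.append(
                ReporterTrack(did, mid, division, t_d[-1], t_d, chans, dict(d_truth))
            )
            truth_rows.append(
                {"cell_id": did, "parent_id": mid, "birth_time": division, **d_truth}
            )
            lineage_rows.append(
                {"cell_id": did, "parent_id": mid, "division_time_h": division}
            )

    lineage = pd.DataFrame(lineage_rows, columns=["cell_id", "parent_id", "division_time_h"])
    truth = pd.DataFrame(truth_rows)
    return Cohort(tracks, lineage, truth, cfg, truncation_warning)
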