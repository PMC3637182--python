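"""Two-arm SOD1-like longitudinal cohort simulator.

Generates a vehicle vs treated study with known ground truth: latent
symptom-onset ages, logistic weight growth peaking then declining, wire-hang
performance collapsing from the 60 s ceiling, Bernoulli symptom flags whose
probability ramps after latent onset, Weibull disease death times (treatment
acting multiplicatively on the scale), and a competing constant daily hazard
of non-disease (injection-related) death after a threshold age — so endpoint
derivation and the censored statistics can be validated end to end.

The latent processes are the simplest generative forms that reproduce the
qualitative shapes of a high-copy SOD1-G93A survival study; their defaults
constitute the versioned profile ``sod1_like_v1``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .endpoints import HANG_CAP_S, MouseTimeline, ObservationRecord

BEAM_SIZES_MM = (24, 19, 11)
BEAM_TRIALS = 3


@dataclass
class BeamParams:
    """Fixed effects and variance components of the balance-beam models.

    Latency (s) is Gaussian, slips are Poisson with log link; both share the
    structure intercept + difficulty slope x (24 - beam_mm) + treatment,
    with per-animal random intercepts and difficulty slopes.
    """

    latency_intercept: float = 15.0
    latency_size_slope: float = 1.5  # s per mm below the largest beam
    latency_treatment: float = -5.0
    latency_sd_intercept: float = 3.0
    latency_sd_slope: float = 0.3
    latency_sd_resid: float = 2.0
    slips_intercept: float = 0.2  # log-mean on the largest beam, vehicle
    slips_size_slope: float = 0.15
    slips_treatment: float = -0.5
    slips_sd_intercept: float = 0.3
    slips_sd_slope: float = 0.05
    test_age_days: int = 119  # ~17 weeks


@dataclass
class CohortConfig:
    n_per_arm: int = 48
    # observation calendar: 2 sessions/week for ages 42-63 d, 3/week after
    schedule_start_day: int = 42
    schedule_switch_day: int = 63
    schedule_end_day: int = 200
    # disease death: Weibull(shape, scale), treated scale x time ratio
    weibull_shape: float = 8.0
    weibull_scale_control: float = 160.0
    treatment_time_ratio: float = 1.0
    # latent symptom onset
    onset_mean: float = 65.0
    onset_sd: float = 8.0
    onset_shift_treated: float = 6.0
    symptom_prob_baseline: float = 0.0
    symptom_prob_ramp: float = 0.08  # per-day probability increase after onset
    # weight trajectory
    weight_asymptote_mean_g: float = 25.0
    weight_asymptote_sd_g: float = 2.0
    weight_growth_midpoint_day: float = 35.0
    weight_growth_tau_days: float = 12.0
    weight_peak_age_mean: float = 100.0
    weight_peak_age_sd: float = 8.0
    weight_decline_rate: float = 0.005  # fraction of peak lost per day
    weight_noise_sd: float = 0.3
    # wire hang
    hang_decline_age_mean: float = 95.0
    hang_decline_age_sd: float = 8.0
    hang_decline_rate: float = 1.5  # s/day
    hang_noise_sd: float = 3.0
    # non-disease (injection-related) deaths
    injection_death_rate: float = 0.006  # daily hazard
    injection_death_min_age: float = 110.0
    beam_params: BeamParams = field(default_factory=BeamParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.treatment_time_ratio <= 0:
            raise ValueError("treatment_time_ratio must be > 0")
        for name in (
            "onset_sd", "symptom_prob_ramp", "weight_noise_sd", "hang_noise_sd",
            "injection_death_rate", "weibull_shape", "weibull_scale_control",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.schedule_start_day < self.schedule_switch_day < self.schedule_end_day):
            raise ValueError("schedule days must be strictly increasing")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "beam_params" in d and isinstance(d["beam_params"], dict):
            d["beam_params"] = BeamParams(**d["beam_params"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown profile keys: {sorted(unknown)}")
        return cls(**d)


def load_profile(name: str = "sod1_like_v1") -> CohortConfig:
    """Load a named parameter profile bundled with the package."""
    ref = resources.files("alsquant") / "profiles" / f"{name}.yaml"
    return CohortConfig.from_dict(yaml.safe_load(ref.read_text()))


@dataclass
class SimulatedMouse:
    mouse_id: str
    arm: str  # "vehicle" | "treated"
    latent_onset_age: float
    latent_death_age: float  # disease death (Weibull draw)
    nondisease_death_age: float | None
    timeline: MouseTimeline
    true_cause: str  # "disease" | "injection"

    @property
    def death_age(self) -> float:
        if self.nondisease_death_age is not None:
            return min(self.latent_death_age, self.nondisease_death_age)
        return self.latent_death_age


def observation_schedule(config: CohortConfig) -> list[int]:
    """Integer observation ages: 2 evenly spaced sessions/week up to the
    switch day, 3/week after (exact weekdays are not modelled)."""
    ages: list[int] = []
    day = config.schedule_start_day
    while day < config.schedule_switch_day:
        ages += [day, day + 4]
        day += 7
    day = config.schedule_switch_day
    while day <= config.schedule_end_day:
        ages += [day, day + 2, day + 5]
        day += 7
    return sorted(a for a in set(ages) if a <= config.schedule_end_day)


def _weight_trend(t, asymptote, midpoint, tau, peak_age, decline_rate):
    peak_w = asymptote / (1.0 + np.exp(-(peak_age - midpoint) / tau))
    if t <= peak_age:
        return asymptote / (1.0 + np.exp(-(t - midpoint) / tau))
    return peak_w * max(0.05, 1.0 - decline_rate * (t - peak_age))


def simulate_mouse(config, rng, mouse_id, arm) -> SimulatedMouse:
    treated = arm == "treated"
    onset = rng.normal(
        config.onset_mean + (config.onset_shift_treated if treated else 0.0),
        config.onset_sd,
    )
    scale = config.weibull_scale_control * (
        config.treatment_time_ratio if treated else 1.0
    )
    death = scale * rng.weibull(config.weibull_shape)
    nondisease = None
    if config.injection_death_rate > 0:
        candidate = config.injection_death_min_age + rng.exponential(
            1.0 / config.injection_death_rate
        )
        if candidate < death:
            nondisease = candidate
    end = min(death, nondisease if nondisease is not None else np.inf)
    cause = "injection" if nondisease is not None else "disease"

    asymptote = max(10.0, rng.normal(config.weight_asymptote_mean_g, config.weight_asymptote_sd_g))
    peak_age = rng.normal(config.weight_peak_age_mean, config.weight_peak_age_sd)
    hang_decline = rng.normal(config.hang_decline_age_mean, config.hang_decline_age_sd)

    records = []
    for age in observation_schedule(config):
        if age >= end:
            break
        w = _weight_trend(
            age, asymptote, config.weight_growth_midpoint_day,
            config.weight_growth_tau_days, peak_age, config.weight_decline_rate,
        )
        w = max(1.0, w + rng.normal(0.0, config.weight_noise_sd))
        p = config.symptom_prob_baseline
        if age > onset:
            p += config.symptom_prob_ramp * (age - onset)
        p = min(1.0, max(0.0, p))
        tremor = bool(rng.random() < p)
        extension_loss = bool(rng.random() < p)
        latent_hang = HANG_CAP_S
        if age > hang_decline:
            latent_hang = HANG_CAP_S - config.hang_decline_rate * (age - hang_decline)
        if latent_hang >= HANG_CAP_S:
            hangs = [HANG_CAP_S] * 3  # ceiling performance is reliable
        else:
            hangs = list(
                np.clip(latent_hang + rng.normal(0, config.hang_noise_sd, 3), 0, HANG_CAP_S)
            )
        # righting stays prompt until the final week of disease
        righting = 1.0
        if cause == "disease" and age > death - 7:
            righting = 1.0 + 3.0 * (age - (death - 7))
        records.append(
            ObservationRecord(
                mouse_id=mouse_id,
                age_days=age,
                weight_g=w,
                tremor=tremor,
                extension_loss=extension_loss,
                hang_latencies_s=hangs,
                righting_s=righting,
            )
        )
    return SimulatedMouse(
        mouse_id=mouse_id,
        arm=arm,
        latent_onset_age=float(onset),
        latent_death_age=float(death),
        nondisease_death_age=None if nondisease is None else float(nondisease),
        timeline=MouseTimeline(mouse_id=mouse_id, records=records),
        true_cause=cause,
    )


def simulate_cohort(config: CohortConfig) -> tuple[list[SimulatedMouse], dict]:
    """Simulate both arms (balanced to ``n_per_arm`` exactly); returns the
    mice plus a ground-truth parameter record. Deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mice = []
    for arm in ("vehicle", "treated"):
        for i in range(config.n_per_arm):
            mouse_id = f"{'V' if arm == 'vehicle' else 'T'}{i + 1:03d}"
            mice.append(simulate_mouse(config, rng, mouse_id, arm))
    truth = {"config": asdict(config)}
    return mice, truth


def timelines_frame(mice: list[SimulatedMouse]) -> pd.DataFrame:
    rows = []
    for m in mice:
        for r in m.timeline.records:
            h = list(r.hang_latencies_s) + [np.nan] * (3 - len(r.hang_latencies_s))
            rows.append(
                {
                    "mouse_id": m.mouse_id,
                    "arm": m.arm,
                    "age_days": r.age_days,
                    "weight_g": r.weight_g,
                    "tremor": r.tremor,
                    "extension_loss": r.extension_loss,
                    "hang1_s": h[0],
                    "hang2_s": h[1],
                    "hang3_s": h[2],
                    "righting_s": r.righting_s,
                }
            )
    return pd.DataFrame(rows)


def survival_frame(mice: list[SimulatedMouse]) -> pd.DataFrame:
    """One row per mouse: age at death/censor, event flag (injection-related
    deaths are censored, mirroring the non-disease-death taxonomy)."""
    return pd.DataFrame(
        {
            "mouse_id": [m.mouse_id for m in mice],
            "arm": [m.arm for m in mice],
            "age_days": [m.death_age for m in mice],
            "event": [m.true_cause == "disease" for m in mice],
            "cause": [m.true_cause for m in mice],
        }
    )


def simulate_beam(config: CohortConfig, mice: list[SimulatedMouse]) -> pd.DataFrame:
    """Balance-beam session: 3 trials on each of the 3 beams for every mouse
    still alive at the test age. Latency from the linear mixed model, slips
    from the Poisson log-linear mixed model; 9 rows per tested mouse."""
    bp = config.beam_params
    rng = np.random.default_rng(config.seed + 500_009)
    rows = []
    for m in mice:
        if m.death_age <= bp.test_age_days:
            continue
        treated = 1.0 if m.arm == "treated" else 0.0
        a_lat = rng.normal(0, bp.latency_sd_intercept)
        b_lat = rng.normal(0, bp.latency_sd_slope)
        a_slip = rng.normal(0, bp.slips_sd_intercept)
        b_slip = rng.normal(0, bp.slips_sd_slope)
        for size in BEAM_SIZES_MM:
            diff = float(BEAM_SIZES_MM[0] - size)  # mm below the largest beam
            mu_lat = (
                bp.latency_intercept + bp.latency_size_slope * diff
                + bp.latency_treatment * treated + a_lat + b_lat * diff
            )
            log_mu_slip = (
                bp.slips_intercept + bp.slips_size_slope * diff
                + bp.slips_treatment * treated + a_slip + b_slip * diff
            )
            for trial in range(1, BEAM_TRIALS + 1):
                rows.append(
                    {
                        "mouse_id": m.mouse_id,
                        "arm": m.arm,
                        "beam_mm": size,
                        "trial": trial,
                        "latency_s": max(1.0, mu_lat + rng.normal(0, bp.latency_sd_resid)),
                        "slips": int(rng.poisson(np.exp(log_mu_slip))),
                    }
                )
    return pd.DataFrame(rows)
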