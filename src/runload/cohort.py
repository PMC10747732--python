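"""Synthetic runner cohort, stride kinematics and ground-truth tissue loads.

This module generates the inputs the prediction pipeline is trained on:

* a heterogeneous cohort of runners with per-sex anthropometrics,
* treadmill trials over a 6-20 km/h speed range with a cadence law,
* per-trial periodic segment kinematics expressed as truncated Fourier
  series of the stride frequency, and
* peak patella-ligament and Achilles-tendon forces from a declared
  quasi-static force model.

The force model is deliberately simple and fully declared: the stance
vertical ground reaction is a half-sine whose amplitude is fixed by impulse
balance (the mean vertical force over a step equals body weight), joint
moments are lever-arm products of that force with the instantaneous knee
flexion (knee) or a strike-style-dependent centre-of-pressure lever (ankle),
and tissue forces are moments divided by anatomical moment arms proportional
to segment lengths.  Everything is controlled by an explicit, versioned
:class:`CohortConfig` so recovery experiments are reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .fourier import FourierCode, N_HARMONICS

GRAVITY = 9.81  # m/s^2

FEMALE = "female"
MALE = "male"
HEEL = "heel"
FOREFOOT = "forefoot"


def derive_seed(master_seed: int, *names) -> int:
    """Deterministic child seed below 2**31 from a master seed and labels."""
    h = hashlib.blake2s(digest_size=8)
    h.update(str(int(master_seed)).encode())
    for name in names:
        h.update(b"/")
        h.update(str(name).encode())
    return int.from_bytes(h.digest(), "big") % (2**31)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexParams:
    """Gaussian anthropometric parameters for one sex."""

    mass_mean: float
    mass_sd: float
    stature_mean: float
    stature_sd: float
    age_mean: float
    age_sd: float


@dataclass(frozen=True)
class CohortConfig:
    """All generator constants, in SI units unless noted.

    Segment lengths are sampled as fixed fractions of stature with a small
    multiplicative jitter; cadence follows an affine step-frequency/speed
    law with a runner-specific offset; the duty factor (ground-contact
    fraction of a step) decreases affinely with speed, clipped to a
    physiological band.
    """

    female: SexParams = SexParams(62.0, 7.0, 1.67, 0.06, 38.0, 10.0)
    male: SexParams = SexParams(78.0, 9.0, 1.80, 0.07, 40.0, 11.0)
    #: cohort sex ratio, default 30 female : 48 male
    female_fraction: float = 30.0 / 78.0

    thigh_ratio: float = 0.245   # thigh length / stature
    shank_ratio: float = 0.246   # shank length / stature
    foot_ratio: float = 0.152    # foot length / stature
    segment_jitter_sd: float = 0.02  # multiplicative, per segment

    speed_range: tuple = (6.0, 20.0)  # km/h
    n_trials_default: int = 285

    # step frequency (Hz) = intercept + slope * speed_kmh + runner offset
    step_freq_intercept: float = 2.40
    step_freq_slope: float = 0.04
    step_freq_runner_sd: float = 0.08

    # duty factor = intercept + slope * speed_kmh, clipped
    duty_intercept: float = 0.486
    duty_slope: float = -0.011
    duty_clip: tuple = (0.20, 0.45)

    forefoot_fraction: float = 0.30

    #: left/right mirror symmetry of the generated gait; asymmetry_factor
    #: scales right-side amplitudes by (1 - asymmetry_factor)
    symmetric: bool = True
    asymmetry_factor: float = 0.0

    #: per-channel multiplicative amplitude jitter between trials
    amplitude_jitter_sd: float = 0.05

    #: optional additive accelerometer noise (m/s^2); default none, the
    #: pipeline works on perfect virtual accelerations
    noise_sd: float = 0.0

    # --- quasi-static force model constants -------------------------------
    #: knee lever arm per radian of knee flexion (m/rad)
    knee_lever_per_rad: float = 0.18
    #: patella ligament moment arm as a fraction of shank length
    r_pat_ratio: float = 0.12
    #: Achilles tendon moment arm as a fraction of foot length
    r_ach_ratio: float = 0.25
    #: ankle lever(t)/foot_length = a + b * (t / t_contact), per strike style
    heel_lever: tuple = (-0.30, 0.90)
    forefoot_lever: tuple = (0.55, 0.05)
    gravity: float = GRAVITY

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunnerProfile:
    runner_id: str
    sex: str
    age: float          # years
    mass: float         # kg
    stature: float      # m
    thigh_length: float  # m
    shank_length: float  # m
    foot_length: float   # m
    bmi: float          # kg/m^2

    def __post_init__(self):
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"unknown sex {self.sex!r}")
        for name in ("mass", "stature", "thigh_length", "shank_length", "foot_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not np.isclose(self.bmi, self.mass / self.stature**2, rtol=1e-9):
            raise ValueError("bmi inconsistent with mass and stature")


@dataclass(frozen=True)
class TrialSpec:
    trial_id: str
    runner_id: str
    speed: float                   # km/h
    stride_period: float           # s (two steps)
    angular_step_frequency: float  # rad/s, 2*pi / step period
    duty_factor: float             # ground-contact fraction of a step
    strike_style: str              # heel | forefoot

    def __post_init__(self):
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must lie in (0, 1)")
        if self.strike_style not in (HEEL, FOREFOOT):
            raise ValueError(f"unknown strike style {self.strike_style!r}")
        step_period = self.stride_period / 2.0
        if not np.isclose(self.angular_step_frequency, 2.0 * np.pi / step_period,
                          rtol=1e-9):
            raise ValueError("angular_step_frequency inconsistent with stride_period")

    @property
    def step_period(self) -> float:
        return self.stride_period / 2.0


@dataclass(frozen=True)
class TrialKinematics:
    """Per-trial band-limited segment kinematics.

    ``channels`` maps channel names (e.g. ``knee_flexion_left``) to
    :class:`FourierCode` objects sharing the stride's fundamental frequency.
    Phase 0 of the cycle is right heel strike; the left heel strikes half a
    stride later.
    """

    trial_id: str
    fundamental_frequency: float  # Hz, 1 / stride period
    channels: dict
    heel_strike_phase: float = 0.0

    @property
    def stride_period(self) -> float:
        return 1.0 / self.fundamental_frequency


@dataclass(frozen=True)
class GroundTruthForces:
    """Peak tissue forces over the cycle, normalized by body mass (N/kg)."""

    trial_id: str
    patella_force_left: float
    patella_force_right: float
    achilles_force_left: float
    achilles_force_right: float

    def __post_init__(self):
        for name in ("patella_force_left", "patella_force_right",
                     "achilles_force_left", "achilles_force_right"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort(n_runners: int, seed: int,
                  config: CohortConfig = CohortConfig()) -> list:
    """Draw ``n_runners`` anthropometric profiles.

    The sex split follows ``config.female_fraction`` deterministically
    (rounded), so the default 78-runner cohort contains exactly 30 female
    and 48 male runners.
    """
    if n_runners < 0:
        raise ValueError("n_runners must be non-negative")
    rng = np.random.default_rng(derive_seed(seed, "cohort"))
    n_female = int(round(n_runners * config.female_fraction))
    sexes = [FEMALE] * n_female + [MALE] * (n_runners - n_female)
    rng.shuffle(sexes)

    profiles = []
    for i, sex in enumerate(sexes):
        p = config.female if sex == FEMALE else config.male
        mass = max(35.0, rng.normal(p.mass_mean, p.mass_sd))
        stature = max(1.40, rng.normal(p.stature_mean, p.stature_sd))
        age = float(np.clip(rng.normal(p.age_mean, p.age_sd), 18.0, 75.0))
        jitters = 1.0 + config.segment_jitter_sd * rng.standard_normal(3)
        thigh = config.thigh_ratio * stature * jitters[0]
        shank = config.shank_ratio * stature * jitters[1]
        foot = config.foot_ratio * stature * jitters[2]
        profiles.append(RunnerProfile(
            runner_id=f"R{i + 1:03d}",
            sex=sex,
            age=age,
            mass=float(mass),
            stature=float(stature),
            thigh_length=float(thigh),
            shank_length=float(shank),
            foot_length=float(foot),
            bmi=float(mass / stature**2),
        ))
    return profiles


def sample_trials(cohort: list, n_trials: int, speed_range=None, seed: int = 0,
                  config: CohortConfig = CohortConfig()) -> list:
    """Assign ``n_trials`` treadmill trials to runners in the cohort.

    Speeds are uniform over ``speed_range``; each runner carries a habitual
    strike style and a personal cadence offset, both seeded.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    if not cohort and n_trials > 0:
        raise ValueError("cannot sample trials from an empty cohort")
    if speed_range is None:
        speed_range = config.speed_range
    lo, hi = float(speed_range[0]), float(speed_range[1])
    if lo > hi:
        raise ValueError("speed_range must be (low, high) with low <= high")

    rng = np.random.default_rng(derive_seed(seed, "trials"))
    # per-runner latent traits
    styles = {}
    cadence_offsets = {}
    for prof in cohort:
        styles[prof.runner_id] = (
            FOREFOOT if rng.random() < config.forefoot_fraction else HEEL
        )
        cadence_offsets[prof.runner_id] = rng.normal(0.0, config.step_freq_runner_sd)

    trials = []
    for j in range(n_trials):
        prof = cohort[int(rng.integers(len(cohort)))]
        speed = float(rng.uniform(lo, hi)) if hi > lo else lo
        f_step = (config.step_freq_intercept + config.step_freq_slope * speed
                  + cadence_offsets[prof.runner_id])
        f_step = max(1.5, f_step)
        step_period = 1.0 / f_step
        duty = float(np.clip(config.duty_intercept + config.duty_slope * speed,
                             *config.duty_clip))
        trials.append(TrialSpec(
            trial_id=f"T{j + 1:04d}",
            runner_id=prof.runner_id,
            speed=speed,
            stride_period=2.0 * step_period,
            angular_step_frequency=2.0 * np.pi * f_step,
            duty_factor=duty,
            strike_style=styles[prof.runner_id],
        ))
    return trials


# ---------------------------------------------------------------------------
# kinematics synthesis
# ---------------------------------------------------------------------------

# Channel templates.  Each entry: dc = (base, slope), harmonics = list of
# (k, base_amp, amp_slope, peak_phase) where the harmonic contributes
# amp * cos(2 pi k (p - peak_phase)) in stride phase p and
# amp = base + slope * u, u = normalized speed in [0, 1].
# Left-leg stance spans stride phase [0.5, 0.5 + duty/2); left swing peaks
# near phase 0.1.  Limb channels are dominated by harmonic 1 (one cycle per
# stride), torso channels by harmonic 2 (one cycle per step).
_LEFT_TEMPLATES = {
    # torso channels carry even stride harmonics only (one cycle per step),
    # which also keeps the symmetric default exactly mirror-symmetric
    "pelvis_vert": {            # m
        "dc": (0.0, 0.0),
        "harmonics": [(2, 0.035, 0.025, 0.60),
                      (4, 0.004, 0.002, 0.55)],
    },
    "pelvis_lat": {             # m
        "dc": (0.0, 0.0),
        "harmonics": [(1, 0.020, 0.010, 0.75),
                      (3, 0.003, 0.001, 0.20)],
    },
    "trunk_lean": {             # rad, forward positive
        "dc": (0.08, 0.06),
        "harmonics": [(2, 0.030, 0.020, 0.58),
                      (4, 0.004, 0.002, 0.50)],
    },
    "hip_flexion_left": {       # rad
        "dc": (0.05, 0.05),
        "harmonics": [(1, 0.35, 0.20, 0.45),
                      (2, 0.06, 0.02, 0.10),
                      (3, 0.02, 0.01, 0.30)],
    },
    "knee_flexion_left": {      # rad
        "dc": (0.60, 0.20),
        "harmonics": [(1, 0.45, 0.20, 0.10),
                      (2, 0.15, 0.10, 0.085),
                      (3, 0.05, 0.02, 0.15),
                      (4, 0.02, 0.01, 0.05),
                      (5, 0.01, 0.005, 0.12)],
    },
    "shoulder_flexion_left": {  # rad, arm anti-phase with ipsilateral leg
        "dc": (0.0, 0.0),
        "harmonics": [(1, 0.30, 0.10, 0.95),
                      (2, 0.05, 0.02, 0.45),
                      (3, 0.015, 0.005, 0.25)],
    },
}

# ankle dorsiflexion templates differ by strike style: forefoot runners
# land plantar-flexed with more step-frequency content
_ANKLE_TEMPLATES = {
    HEEL: {
        "dc": (-0.05, 0.0),
        "harmonics": [(1, 0.25, 0.10, 0.62),
                      (2, 0.10, 0.04, 0.58),
                      (3, 0.03, 0.01, 0.40)],
    },
    FOREFOOT: {
        "dc": (0.12, 0.02),
        "harmonics": [(1, 0.28, 0.12, 0.60),
                      (2, 0.16, 0.06, 0.56),
                      (3, 0.05, 0.02, 0.38)],
    },
}

#: channels shared by both body sides (no mirror copy)
AXIAL_CHANNELS = ("pelvis_vert", "pelvis_lat", "trunk_lean")


def _code_from_template(template: dict, u: float, fundamental: float,
                        jitter_rng, jitter_sd: float,
                        phase_shift: float = 0.0,
                        amp_scale: float = 1.0) -> FourierCode:
    """Build a FourierCode from an amplitude/phase template.

    ``phase_shift`` (in stride-phase units) delays the channel, used to
    derive right-side channels as half-cycle copies of the left.
    """
    dc_base, dc_slope = template["dc"]
    dc = (dc_base + dc_slope * u)
    sine = np.zeros(N_HARMONICS)
    cosine = np.zeros(N_HARMONICS)
    for k, base, slope, peak in template["harmonics"]:
        amp = (base + slope * u) * amp_scale
        if jitter_sd > 0:
            amp *= 1.0 + jitter_sd * jitter_rng.standard_normal()
        theta = 2.0 * np.pi * k * (peak + phase_shift)
        cosine[k - 1] += amp * np.cos(theta)
        sine[k - 1] += amp * np.sin(theta)
    return FourierCode(dc=float(dc), sine=tuple(sine), cosine=tuple(cosine),
                       fundamental_frequency=fundamental)


def synthesize_kinematics(profile: RunnerProfile, trial: TrialSpec, seed: int,
                          config: CohortConfig = CohortConfig()) -> TrialKinematics:
    """Generate band-limited segment kinematics for one trial.

    Amplitudes grow smoothly with speed; ankle channels depend on the
    strike style; right-side limb channels are the left channels delayed by
    half a stride (scaled by the asymmetry factor if configured).  Each
    channel's amplitude jitter is drawn from its own child seed, so channels
    unaffected by the strike style are bit-identical across styles.
    """
    lo, hi = config.speed_range
    u = float(np.clip((trial.speed - lo) / max(hi - lo, 1e-12), 0.0, 1.0))
    fundamental = 1.0 / trial.stride_period
    right_scale = 1.0 if config.symmetric else 1.0 - config.asymmetry_factor

    templates = dict(_LEFT_TEMPLATES)
    templates["ankle_angle_left"] = _ANKLE_TEMPLATES[trial.strike_style]

    channels = {}
    for name, tpl in templates.items():
        jrng = np.random.default_rng(
            [derive_seed(seed, trial.trial_id, name), 0])
        channels[name] = _code_from_template(
            tpl, u, fundamental, jrng, config.amplitude_jitter_sd)
        if name not in AXIAL_CHANNELS:
            rname = name.replace("_left", "_right")
            jrng_r = np.random.default_rng(
                [derive_seed(seed, trial.trial_id, name), 0])
            channels[rname] = _code_from_template(
                tpl, u, fundamental, jrng_r, config.amplitude_jitter_sd,
                phase_shift=0.5, amp_scale=right_scale)
    return TrialKinematics(
        trial_id=trial.trial_id,
        fundamental_frequency=fundamental,
        channels=channels,
        heel_strike_phase=0.0,
    )


# ---------------------------------------------------------------------------
# ground-truth force model
# ---------------------------------------------------------------------------

def _vertical_grf_amplitude(duty_factor: float) -> float:
    """Half-sine amplitude factor A with mean step force = body weight.

    integral of A sin(pi t / t_c) over [0, t_c] equals A * 2 t_c / pi; setting
    this equal to step_period (impulse balance in units of body weight)
    gives A = pi / (2 * duty_factor).
    """
    return np.pi / (2.0 * duty_factor)


def _side_forces(profile: RunnerProfile, trial: TrialSpec, kin: TrialKinematics,
                 side: str, config: CohortConfig, n_samples: int = 201):
    """Peak mass-normalized patella and Achilles forces for one leg."""
    step_period = trial.step_period
    t_c = trial.duty_factor * step_period
    # stance of the given leg: right heel strike at phase 0, left at 0.5
    t0 = 0.0 if side == "right" else 0.5 * trial.stride_period
    tau = np.linspace(0.0, t_c, n_samples)
    amp = _vertical_grf_amplitude(trial.duty_factor)
    # vertical GRF in units of body weight (per unit mass: multiply by g)
    fv = config.gravity * amp * np.sin(np.pi * tau / t_c)

    knee = kin.channels[f"knee_flexion_{side}"].evaluate(t0 + tau)
    d_knee = config.knee_lever_per_rad * knee
    r_pat = config.r_pat_ratio * profile.shank_length
    patella = float(np.max(fv * d_knee) / r_pat)
    patella = max(patella, 0.0)

    a, b = (config.heel_lever if trial.strike_style == HEEL
            else config.forefoot_lever)
    d_ankle = profile.foot_length * (a + b * tau / t_c)
    r_ach = config.r_ach_ratio * profile.foot_length
    achilles = float(np.max(fv * d_ankle) / r_ach)
    achilles = max(achilles, 0.0)
    return patella, achilles


def ground_truth_forces(profile: RunnerProfile, trial: TrialSpec,
                        kin: TrialKinematics,
                        config: CohortConfig = CohortConfig()) -> GroundTruthForces:
    """Peak tissue forces from the declared quasi-static model, in N/kg.

    Vertical GRF is a half-sine over the contact time whose amplitude is set
    by impulse balance; the knee moment is GRF times a lever proportional to
    instantaneous knee flexion, the ankle moment is GRF times a
    strike-style-dependent centre-of-pressure lever scaled by foot length;
    tissue forces are the peak moments divided by moment arms proportional
    to shank (patella) and foot (Achilles) length.  Body mass cancels, so
    the outputs are mass-normalized by construction.
    """
    if not 0.0 < trial.duty_factor < 1.0:
        raise ValueError("duty_factor must lie in (0, 1)")
    pat_l, ach_l = _side_forces(profile, trial, kin, "left", config)
    pat_r, ach_r = _side_forces(profile, trial, kin, "right", config)
    return GroundTruthForces(
        trial_id=trial.trial_id,
        patella_force_left=pat_l,
        patella_force_right=pat_r,
        achilles_force_left=ach_l,
        achilles_force_right=ach_r,
    )
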