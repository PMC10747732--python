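"""Stride segmentation, Fourier compression and design-matrix assembly.

Each sensor channel of each trial is reduced to the 11 Fourier
coefficients of one stride (DC + five cosine + five sine terms), giving
4 channels x 11 = 44 predictors per accelerometer.  Seven sensor
configurations are studied — subsets of {left wrist, right wrist, sternum,
left ankle}; the right ankle is dropped because left/right ankle signals
are mirror-symmetric.  Ten scalar predictors (step frequency, sex, age,
three segment lengths, mass, stature, BMI, speed) are appended, yielding
54 columns for single-sensor and 98 for two-sensor configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MALE, GroundTruthForces, RunnerProfile, TrialSpec
from .fourier import N_COEFFICIENTS, N_HARMONICS, FourierCode, fourier_compress
from .virtual_imu import ACCEL_CHANNELS

__all__ = [
    "SensorConfiguration", "SENSOR_CONFIGURATIONS", "DesignMatrix",
    "SegmentationError", "AssemblyError", "segment_stride",
    "compress_trace", "build_design_matrix", "full_matrix_schema",
    "ADDITIONAL_PREDICTORS", "COEFFICIENTS_PER_CHANNEL",
    "COLUMNS_PER_SITE", "acceleration_column_names",
]

#: canonical ordering of retained sites in column layout
RETAINED_SITES = ("left_wrist", "right_wrist", "sternum", "left_ankle")

COEFFICIENTS_PER_CHANNEL = N_COEFFICIENTS          # 11
COLUMNS_PER_SITE = len(ACCEL_CHANNELS) * N_COEFFICIENTS  # 4 * 11 = 44

#: the ten scalar predictors appended to every design matrix
ADDITIONAL_PREDICTORS = (
    "step_frequency", "sex", "age", "thigh_length", "shank_length",
    "foot_length", "body_mass", "stature", "bmi", "speed",
)


class SegmentationError(ValueError):
    """Raised when a series cannot be cut into strides."""


class AssemblyError(KeyError):
    """Raised when a design matrix misses sensor codes for some trial."""


@dataclass(frozen=True)
class SensorConfiguration:
    """One of the seven studied accelerometer placements."""

    config_id: int
    sites: tuple

    def __post_init__(self):
        if "right_ankle" in self.sites:
            raise ValueError("the right ankle placement is not retained")
        unknown = set(self.sites) - set(RETAINED_SITES)
        if unknown:
            raise ValueError(f"unknown sites {sorted(unknown)}")

    @property
    def n_acceleration_columns(self) -> int:
        return COLUMNS_PER_SITE * len(self.sites)

    @property
    def label(self) -> str:
        short = {"left_wrist": "lw", "right_wrist": "rw",
                 "sternum": "ste", "left_ankle": "ank"}
        return "+".join(short[s] for s in self.sites)


#: the seven combinations investigated, in their published order
SENSOR_CONFIGURATIONS = {
    1: SensorConfiguration(1, ("left_wrist",)),
    2: SensorConfiguration(2, ("left_wrist", "right_wrist")),
    3: SensorConfiguration(3, ("left_wrist", "sternum")),
    4: SensorConfiguration(4, ("left_wrist", "left_ankle")),
    5: SensorConfiguration(5, ("sternum", "left_ankle")),
    6: SensorConfiguration(6, ("left_ankle",)),
    7: SensorConfiguration(7, ("sternum",)),
}


# ---------------------------------------------------------------------------
# stride segmentation and compression
# ---------------------------------------------------------------------------

def segment_stride(times: np.ndarray, values: np.ndarray,
                   events: np.ndarray, n_out: int | None = None):
    """Extract one stride (heel strike to heel strike) from a series.

    Returns ``(grid, window)`` where ``grid`` is a uniform time axis over
    [0, stride) relative to the first event, endpoint excluded, and
    ``window`` the series resampled onto it by linear interpolation.

    Parameters
    ----------
    times, values:
        The sampled series.
    events:
        Right-heel-strike times; the window spans the first two.
    n_out:
        Output samples; defaults to the native count inside the stride.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    events = np.sort(np.asarray(events, dtype=float))
    if events.size < 2:
        raise SegmentationError("need at least two heel-strike events")
    e0, e1 = events[0], events[1]
    if not (e1 > e0):
        raise SegmentationError("heel-strike events must be strictly increasing")
    if n_out is None:
        n_out = max(int(np.sum((times >= e0) & (times < e1))), N_COEFFICIENTS)
    grid = e0 + (e1 - e0) * np.arange(n_out) / n_out
    window = np.interp(grid, times, values)
    return grid - e0, window


def compress_trace(trace, fundamental_frequency: float) -> dict:
    """Fourier-compress all four channels of an :class:`AccelTrace`."""
    return {
        ch: fourier_compress(trace.channel(ch), fundamental_frequency)
        for ch in ACCEL_CHANNELS
    }


# ---------------------------------------------------------------------------
# column naming and design-matrix assembly
# ---------------------------------------------------------------------------

def _coefficient_names():
    names = ["dc"]
    names += [f"cos{k}" for k in range(1, N_HARMONICS + 1)]
    names += [f"sin{k}" for k in range(1, N_HARMONICS + 1)]
    return names


def acceleration_column_names(sites) -> list:
    """Stable column names: ``<site>_<channel>_<coef>`` in canonical order."""
    cols = []
    ordered = [s for s in RETAINED_SITES if s in sites]
    for site in ordered:
        for ch in ACCEL_CHANNELS:
            for coef in _coefficient_names():
                cols.append(f"{site}_{ch}_{coef}")
    return cols


@dataclass
class DesignMatrix:
    """Trials-by-predictors table plus mass-normalized peak-force targets."""

    config: SensorConfiguration
    X: pd.DataFrame
    targets: pd.DataFrame  # columns: patella, achilles (N/kg, left side)
    trial_ids: list

    @property
    def column_names(self) -> list:
        return list(self.X.columns)


def _additional_row(profile: RunnerProfile, trial: TrialSpec) -> dict:
    return {
        "step_frequency": trial.angular_step_frequency / (2.0 * np.pi),  # Hz
        "sex": 1.0 if profile.sex == MALE else 0.0,
        "age": profile.age,
        "thigh_length": profile.thigh_length,
        "shank_length": profile.shank_length,
        "foot_length": profile.foot_length,
        "body_mass": profile.mass,
        "stature": profile.stature,
        "bmi": profile.bmi,
        "speed": trial.speed,
    }


def build_design_matrix(trials, accel_codes: dict, profiles: dict,
                        config: SensorConfiguration,
                        forces: dict | None = None) -> DesignMatrix:
    """Assemble the predictor table for one sensor configuration.

    Parameters
    ----------
    trials:
        Sequence of :class:`TrialSpec`; row order follows this sequence.
    accel_codes:
        ``accel_codes[trial_id][site][channel]`` -> :class:`FourierCode`.
    profiles:
        ``runner_id`` -> :class:`RunnerProfile`.
    config:
        The sensor configuration whose sites are included.
    forces:
        Optional ``trial_id`` -> :class:`GroundTruthForces`; when given the
        left-side peak forces become the targets.

    An empty trial list yields an empty frame that still carries the full
    54- or 98-name header.
    """
    accel_cols = acceleration_column_names(config.sites)
    all_cols = accel_cols + list(ADDITIONAL_PREDICTORS)
    ordered_sites = [s for s in RETAINED_SITES if s in config.sites]

    rows, target_rows, trial_ids = [], [], []
    for trial in trials:
        try:
            per_site = accel_codes[trial.trial_id]
        except KeyError:
            raise AssemblyError(
                f"no sensor codes for trial {trial.trial_id}") from None
        row = {}
        for site in ordered_sites:
            if site not in per_site:
                raise AssemblyError(
                    f"trial {trial.trial_id} has no codes for site {site!r}")
            for ch in ACCEL_CHANNELS:
                code: FourierCode = per_site[site][ch]
                row[f"{site}_{ch}_dc"] = code.dc
                for k in range(1, N_HARMONICS + 1):
                    row[f"{site}_{ch}_cos{k}"] = code.cosine[k - 1]
                    row[f"{site}_{ch}_sin{k}"] = code.sine[k - 1]
        row.update(_additional_row(profiles[trial.runner_id], trial))
        rows.append(row)
        trial_ids.append(trial.trial_id)
        if forces is not None:
            f: GroundTruthForces = forces[trial.trial_id]
            target_rows.append({"patella": f.patella_force_left,
                                "achilles": f.achilles_force_left})

    X = pd.DataFrame(rows, columns=all_cols, dtype=float)
    targets = pd.DataFrame(target_rows, columns=["patella", "achilles"],
                           dtype=float)
    if X.shape[0] and X.isna().any().any():
        missing = X.columns[X.isna().any()].tolist()
        raise AssemblyError(f"missing values in columns {missing}")
    return DesignMatrix(config=config, X=X, targets=targets,
                        trial_ids=trial_ids)


# ---------------------------------------------------------------------------
# schema accounting of the full study table
# ---------------------------------------------------------------------------

def full_matrix_schema(n_kinematic_dofs: int = 88, n_accelerometers: int = 5,
                       n_channels: int = 4,
                       n_coefficients: int = N_COEFFICIENTS,
                       n_force_columns: int = 4,
                       n_anthropometric_columns: int = 35,
                       n_scalar_columns: int = 2) -> dict:
    """Column accounting of the full data table the study assembles.

    The anatomical model carries 88 kinematic degrees of freedom and five
    accelerometers with four channels each, all compressed to 11 Fourier
    coefficients; four peak-force columns, 35 anthropometric columns and
    two scalars (speed, angular step frequency) complete the table.  Only
    the acceleration block of the four retained placements plus ten
    anthropometric/scalar predictors feed the prediction models.
    """
    kinematic = n_kinematic_dofs * n_coefficients
    acceleration = n_accelerometers * n_channels * n_coefficients
    per_site = n_channels * n_coefficients
    schema = {
        "kinematic_columns": kinematic,
        "acceleration_columns": acceleration,
        "acceleration_columns_per_site": per_site,
        "acceleration_columns_two_sites": 2 * per_site,
        "retained_acceleration_columns": (n_accelerometers - 1) * per_site,
        "force_columns": n_force_columns,
        "anthropometric_columns": n_anthropometric_columns,
        "scalar_columns": n_scalar_columns,
        "total_columns": (kinematic + acceleration + n_force_columns
                          + n_anthropometric_columns + n_scalar_columns),
        "predictors_single_sensor": per_site + len(ADDITIONAL_PREDICTORS),
        "predictors_double_sensor": 2 * per_site + len(ADDITIONAL_PREDICTORS),
    }
    return schema
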