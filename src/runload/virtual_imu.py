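"""Virtual three-axis accelerometers on a simplified runner body model.

The body is a sagittal-plane segment chain (trunk and arms above a pelvis
root, thigh-shank-foot legs below) driven by the periodic joint channels
from :mod:`runload.cohort`; mediolateral pelvis sway adds an out-of-plane
component.  Five attachment sites — the two wrists, the two ankles and the
sternum — carry segment-fixed sensor frames with the convention x anterior,
y along the segment long axis (proximal), z lateral.

A virtual accelerometer reads proper acceleration: the kinematic
acceleration of its attachment point minus gravity, rotated into the sensor
frame, so a static sensor reads +1 g along the world-up component of its
frame.  Accelerations are obtained by spectral (FFT) differentiation of the
periodic attachment-point trajectory, which is exact for band-limited
motion and spectrally accurate for the smooth trajectories produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import GRAVITY, RunnerProfile, TrialKinematics
from .fourier import N_HARMONICS

SITE_NAMES = ("left_wrist", "right_wrist", "sternum", "left_ankle", "right_ankle")
ACCEL_CHANNELS = ("ax", "ay", "az", "amag")
DEFAULT_SAMPLE_RATE = 300.0  # Hz

_GRAVITY_VEC = np.array([0.0, -GRAVITY, 0.0])


# ---------------------------------------------------------------------------
# chain description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentDef:
    """One rigid segment of the planar chain.

    ``kind`` fixes how the world tilt angle maps to geometry:
    ``root`` (no extent), ``up`` (extends along +y at zero angle, e.g.
    trunk), ``down`` (hangs along -y, e.g. limbs) or ``foot`` (extends
    along +x).  ``angle_terms`` is a linear combination of kinematic
    channels giving the segment's world tilt about the lateral (+z) axis.
    """

    name: str
    length: float
    parent: str | None
    kind: str
    angle_terms: tuple = ()
    offset: tuple = (0.0, 0.0, 0.0)  # constant world offset at the proximal joint


@dataclass(frozen=True)
class AttachmentSite:
    """Sensor mounting: segment, offset and frame in segment coordinates."""

    segment: str
    offset: tuple
    frame: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def frame_matrix(self) -> np.ndarray:
        m = np.asarray(self.frame, dtype=float)
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise ValueError("site frame must be orthonormal")
        return m


@dataclass(frozen=True)
class SegmentChain:
    """Ordered segments plus the five standard attachment sites."""

    segments: tuple
    sites: dict
    root_height: float

    def __post_init__(self):
        missing = set(SITE_NAMES) - set(self.sites)
        if missing:
            raise ValueError(f"attachment sites missing: {sorted(missing)}")

    def segment(self, name: str) -> SegmentDef:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)


def build_chain(profile: RunnerProfile) -> SegmentChain:
    """Anthropometry-scaled chain for one runner.

    Trunk and arm lengths are fixed fractions of stature; thigh, shank and
    foot lengths come from the profile.  The z axis points to the runner's
    right, so left-side joints sit at negative z.
    """
    st = profile.stature
    trunk_len = 0.30 * st
    arm_len = 0.34 * st
    hip_off = 0.055 * st
    shoulder_off = 0.11 * st

    def leg(side: str, sign: float):
        return (
            SegmentDef(f"thigh_{side}", profile.thigh_length, "pelvis", "down",
                       ((f"hip_flexion_{side}", 1.0),),
                       (0.0, 0.0, sign * hip_off)),
            SegmentDef(f"shank_{side}", profile.shank_length, f"thigh_{side}", "down",
                       ((f"hip_flexion_{side}", 1.0),
                        (f"knee_flexion_{side}", -1.0))),
            SegmentDef(f"foot_{side}", profile.foot_length, f"shank_{side}", "foot",
                       ((f"hip_flexion_{side}", 1.0),
                        (f"knee_flexion_{side}", -1.0),
                        (f"ankle_angle_{side}", 1.0))),
        )

    segments = (
        SegmentDef("pelvis", 0.0, None, "root"),
        SegmentDef("trunk", trunk_len, "pelvis", "up", (("trunk_lean", 1.0),)),
        SegmentDef("arm_left", arm_len, "trunk", "down",
                   (("trunk_lean", 1.0), ("shoulder_flexion_left", 1.0)),
                   (0.0, 0.0, -shoulder_off)),
        SegmentDef("arm_right", arm_len, "trunk", "down",
                   (("trunk_lean", 1.0), ("shoulder_flexion_right", 1.0)),
                   (0.0, 0.0, shoulder_off)),
        *leg("left", -1.0),
        *leg("right", 1.0),
    )
    sites = {
        "left_wrist": AttachmentSite("arm_left", (0.02, -0.95 * arm_len, -0.01)),
        "right_wrist": AttachmentSite("arm_right", (0.02, -0.95 * arm_len, 0.01)),
        "sternum": AttachmentSite("trunk", (0.03, 0.65 * trunk_len, 0.0)),
        "left_ankle": AttachmentSite("foot_left",
                                     (0.20 * profile.foot_length, 0.03, -0.01)),
        "right_ankle": AttachmentSite("foot_right",
                                      (0.20 * profile.foot_length, 0.03, 0.01)),
    }
    return SegmentChain(segments=segments, sites=sites, root_height=0.53 * st)


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def _direction(kind: str, angle: np.ndarray) -> np.ndarray:
    """Proximal-to-distal unit vector for a segment tilt (N,) -> (N,3)."""
    s, c = np.sin(angle), np.cos(angle)
    z = np.zeros_like(angle)
    if kind == "up":
        return np.stack([s, c, z], axis=-1)
    if kind == "down":
        return np.stack([s, -c, z], axis=-1)
    if kind == "foot":
        return np.stack([c, s, z], axis=-1)
    raise ValueError(f"unknown segment kind {kind!r}")


def _rotations(kind: str, angle: np.ndarray) -> np.ndarray:
    """Segment frame (columns x, y, z in world) at every sample, (N,3,3).

    The sensor convention is x anterior, y along the long axis pointing
    proximally (limbs) or cranially (trunk), z lateral.
    """
    s, c = np.sin(angle), np.cos(angle)
    n = angle.shape[0]
    rot = np.zeros((n, 3, 3))
    rot[:, 2, 2] = 1.0
    if kind in ("down", "foot", "root"):
        # R_z(angle): x = (c, s, 0), y = (-s, c, 0)
        rot[:, 0, 0], rot[:, 1, 0] = c, s
        rot[:, 0, 1], rot[:, 1, 1] = -s, c
    elif kind == "up":
        # R_z(-angle): x = (c, -s, 0), y = (s, c, 0)
        rot[:, 0, 0], rot[:, 1, 0] = c, -s
        rot[:, 0, 1], rot[:, 1, 1] = s, c
    else:
        raise ValueError(f"unknown segment kind {kind!r}")
    return rot


@dataclass
class SegmentPose:
    """World pose series of one segment over the time grid."""

    name: str
    kind: str
    proximal: np.ndarray  # (N, 3) world position of the proximal joint
    angle: np.ndarray     # (N,) world tilt about +z
    length: float

    @property
    def rotations(self) -> np.ndarray:
        return _rotations(self.kind, self.angle)

    @property
    def distal(self) -> np.ndarray:
        return self.proximal + self.length * _direction(self.kind, self.angle) \
            if self.kind != "root" else self.proximal


@dataclass
class PoseSet:
    """Forward-kinematics output: per-segment poses on a shared grid."""

    time_grid: np.ndarray
    segments: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> SegmentPose:
        return self.segments[name]


def forward_kinematics(chain: SegmentChain, kin: TrialKinematics,
                       time_grid: np.ndarray) -> PoseSet:
    """Pose every segment of the chain at the given uniform times.

    The pelvis root translates with the ``pelvis_vert`` and ``pelvis_lat``
    channels; every other segment's world tilt is the configured linear
    combination of joint channels, so poses are continuous and exactly
    periodic over the stride.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size < 2:
        raise ValueError("time grid needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("time grid must be uniform")

    values = {name: code.evaluate(t) for name, code in kin.channels.items()}
    zeros = np.zeros_like(t)

    root_pos = np.stack([
        zeros,
        chain.root_height + values.get("pelvis_vert", zeros),
        values.get("pelvis_lat", zeros),
    ], axis=-1)

    poses = PoseSet(time_grid=t)
    for seg in chain.segments:
        if seg.kind == "root":
            poses.segments[seg.name] = SegmentPose(
                seg.name, "root", root_pos, zeros.copy(), 0.0)
            continue
        parent = poses.segments[seg.parent]
        prox = parent.distal + np.asarray(seg.offset, dtype=float)
        angle = zeros.copy()
        for channel, coeff in seg.angle_terms:
            angle = angle + coeff * values[channel]
        poses.segments[seg.name] = SegmentPose(
            seg.name, seg.kind, prox, angle, seg.length)
    return poses


# ---------------------------------------------------------------------------
# sensor emulation
# ---------------------------------------------------------------------------

@dataclass
class AccelTrace:
    """Segment-frame proper acceleration of one virtual sensor (m/s^2)."""

    site: str
    time_grid: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    amag: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        if name not in ACCEL_CHANNELS:
            raise KeyError(name)
        return getattr(self, name)


def spectral_acceleration(positions: np.ndarray, period: float) -> np.ndarray:
    """Second time derivative of a periodic trajectory by FFT.

    ``positions`` is (N, 3) sampled uniformly over one period with the
    endpoint excluded; differentiation multiplies each Fourier mode by
    -(2 pi f)^2, which is exact for band-limited signals.
    """
    p = np.asarray(positions, dtype=float)
    n = p.shape[0]
    freqs = np.fft.rfftfreq(n, d=period / n)
    factor = -((2.0 * np.pi * freqs) ** 2)
    return np.fft.irfft(np.fft.rfft(p, axis=0) * factor[:, None], n=n, axis=0)


def proper_acceleration(positions: np.ndarray, rotations: np.ndarray,
                        period: float,
                        gravity: np.ndarray = _GRAVITY_VEC) -> np.ndarray:
    """Sensor-frame specific force a_kin - g for a periodic trajectory.

    A static sensor (constant position) reads ``-g`` expressed in its own
    frame, i.e. +9.81 on whichever sensor axis points up.
    """
    accel_world = spectral_acceleration(positions, period) - np.asarray(gravity)
    # rows of R^T dot the world vector: einsum over world index
    return np.einsum("nij,nj->ni", np.transpose(rotations, (0, 2, 1)), accel_world)


def site_positions(poses: PoseSet, chain: SegmentChain, site: str):
    """World positions and sensor frames of an attachment site."""
    try:
        att = chain.sites[site]
    except KeyError:
        raise KeyError(f"unknown attachment site {site!r}") from None
    seg = poses[att.segment]
    rot = seg.rotations
    local = att.frame_matrix()
    positions = seg.proximal + np.einsum("nij,j->ni", rot,
                                         np.asarray(att.offset, dtype=float))
    return positions, rot @ local


def sensor_acceleration(poses: PoseSet, chain: SegmentChain, site: str,
                        gravity: np.ndarray = _GRAVITY_VEC) -> AccelTrace:
    """Emulate one virtual accelerometer from segment poses.

    The pose grid must cover exactly one stride with the endpoint excluded
    (as produced by :func:`emulate_all_sites`), so the trajectory seen by
    the FFT is exactly periodic.
    """
    t = poses.time_grid
    dt = t[1] - t[0]
    period = t.size * dt
    positions, frames = site_positions(poses, chain, site)
    local = proper_acceleration(positions, frames, period, gravity)
    amag = np.sqrt(np.sum(local**2, axis=1))
    return AccelTrace(site=site, time_grid=t.copy(),
                      ax=local[:, 0], ay=local[:, 1], az=local[:, 2], amag=amag)


def traces_to_frame(trial_id: str, traces: dict):
    """Long-format table (trial_id, site, channel, t, value) of all traces."""
    import pandas as pd

    rows = []
    for site, trace in traces.items():
        for ch in ACCEL_CHANNELS:
            values = trace.channel(ch)
            rows.append(pd.DataFrame({
                "trial_id": trial_id, "site": site, "channel": ch,
                "t": trace.time_grid, "value": values,
            }))
    return pd.concat(rows, ignore_index=True)


def emulate_all_sites(chain: SegmentChain, kin: TrialKinematics,
                      sample_rate: float = DEFAULT_SAMPLE_RATE,
                      gravity: np.ndarray = _GRAVITY_VEC,
                      noise_sd: float = 0.0, seed: int = 0) -> dict:
    """Emulate all five virtual accelerometers for one trial.

    Samples one stride at ``sample_rate`` (endpoint excluded).  The rate
    must resolve at least the fifth stride harmonic.  Optional additive
    Gaussian noise models imperfect sensors; by default the accelerations
    are noise-free.
    """
    period = kin.stride_period
    n = int(round(sample_rate * period))
    if n < 2 * N_HARMONICS + 1:
        raise ValueError(
            f"sample rate {sample_rate} Hz resolves fewer than "
            f"{N_HARMONICS} harmonics of the stride")
    t = np.arange(n) * period / n
    poses = forward_kinematics(chain, kin, t)
    traces = {}
    rng = np.random.default_rng(seed)
    for site in SITE_NAMES:
        trace = sensor_acceleration(poses, chain, site, gravity)
        if noise_sd > 0:
            for ch in ("ax", "ay", "az"):
                arr = getattr(trace, ch)
                arr += rng.normal(0.0, noise_sd, size=arr.shape)
            trace.amag = np.sqrt(trace.ax**2 + trace.ay**2 + trace.az**2)
        traces[site] = trace
    return traces
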