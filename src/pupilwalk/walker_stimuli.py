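"""Emotional point-light walker stimuli and their transforms.

A walker is a 15-dot point-light display (head, thorax, pelvis and the
major joints) animated by a stylized parametric gait model: each marker
follows a two-harmonic sinusoidal trajectory (fundamental gait frequency
plus first overtone) around a static skeleton.  The walker's emotional
state is a score on a happy--sad axis (happy = +6, neutral = 0,
sad = -6, in SD units of that axis); the score linearly interpolates
cadence, limb amplitude and posture between a slouching, slow sad gait
and a bouncy, fast happy gait.  After synthesis the gait frequency is
rescaled so that the mean per-dot speed matches the per-emotion target
speed (happy 5.76, neutral 4.14, sad 3.21 pixels/frame).

Three transforms operate on a generated sequence:

``invert``
    vertical mirror flip about the display box midline (upside-down
    walker, identical low-level features);
``scramble``
    rigid translation of each dot's whole trajectory to a random
    start position inside the walker's bounding box (local motion
    preserved, global form destroyed);
``remove_acceleration``
    equal-arc-length reparameterization of each dot's path so the dot
    travels its original trajectory at constant speed (trajectories
    preserved, local kinematics destroyed).

Coordinates are screen pixels, origin top-left, y increasing downward;
frames are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_LABELS",
    "EMOTION_SPEED_ANCHORS",
    "WalkerConfig",
    "PointLightSequence",
    "generate_walker",
    "invert",
    "scramble",
    "remove_acceleration",
    "mean_dot_speed",
    "write_frame_table",
    "read_frame_table",
]

#: The 15 point-light markers, top to bottom.
MARKER_LABELS: tuple[str, ...] = (
    "head",
    "thorax",
    "pelvis",
    "l_shoulder",
    "r_shoulder",
    "l_elbow",
    "r_elbow",
    "l_wrist",
    "r_wrist",
    "l_hip",
    "r_hip",
    "l_knee",
    "r_knee",
    "l_ankle",
    "r_ankle",
)

#: Calibrated mean dot speed (pixels/frame) at the three emotion anchors.
EMOTION_SPEED_ANCHORS: dict[float, float] = {-6.0: 3.21, 0.0: 4.14, 6.0: 5.76}


def speed_for_emotion(emotion_score: float) -> float:
    """Target mean dot speed (px/frame), piecewise-linear between anchors."""
    e = float(emotion_score)
    if e <= 0:
        lo, hi = EMOTION_SPEED_ANCHORS[-6.0], EMOTION_SPEED_ANCHORS[0.0]
        return lo + (e + 6.0) / 6.0 * (hi - lo)
    lo, hi = EMOTION_SPEED_ANCHORS[0.0], EMOTION_SPEED_ANCHORS[6.0]
    return lo + e / 6.0 * (hi - lo)


@dataclass(frozen=True)
class WalkerConfig:
    """Parameters of one emotional walker animation.

    ``emotion_score`` lives on the happy--sad axis in SD units
    (happy = +6, neutral = 0, sad = -6).  ``target_mean_speed`` defaults
    to the per-emotion calibration speed; ``display_box`` is the pixel
    rectangle (x0, y0, x1, y1) the walker is shown in.
    """

    emotion_score: float = 0.0
    direction: str = "right45"
    n_frames: int = 240
    frame_rate: float = 60.0
    target_mean_speed: float | None = None
    display_box: tuple[float, float, float, float] = (0.0, 0.0, 1920.0, 1080.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.emotion_score):
            raise ValueError("emotion_score must be finite")
        if not -6.0 <= self.emotion_score <= 6.0:
            raise ValueError("emotion_score must lie in [-6, +6]")
        if self.direction not in ("left45", "right45"):
            raise ValueError("direction must be 'left45' or 'right45'")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.target_mean_speed is not None and self.target_mean_speed <= 0:
            raise ValueError("target_mean_speed must be positive")

    @property
    def resolved_speed(self) -> float:
        if self.target_mean_speed is not None:
            return self.target_mean_speed
        return speed_for_emotion(self.emotion_score)


@dataclass(frozen=True)
class PointLightSequence:
    """Frame-by-frame 2-D coordinates of the 15 walker markers.

    ``positions`` has shape (n_frames, 15, 2) in pixels (x, y; y grows
    downward).  ``display_box`` is carried along so that transforms that
    reference the display geometry (inversion) remain self-contained.
    """

    positions: np.ndarray
    frame_rate: float
    marker_labels: tuple[str, ...] = MARKER_LABELS
    display_box: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[1] != len(self.marker_labels) or pos.shape[2] != 2:
            raise ValueError(
                f"positions must have shape (n_frames, {len(self.marker_labels)}, 2)"
            )
        if len(self.marker_labels) != 15:
            raise ValueError("a point-light walker has exactly 15 markers")
        if pos.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    def bounding_box(self) -> tuple[float, float, float, float]:
        """Axis-aligned box over all frames and dots: (x0, y0, x1, y1)."""
        xy_min = self.positions.reshape(-1, 2).min(axis=0)
        xy_max = self.positions.reshape(-1, 2).max(axis=0)
        return (xy_min[0], xy_min[1], xy_max[0], xy_max[1])


def mean_dot_speed(seq: PointLightSequence) -> float:
    """Mean per-frame displacement magnitude, averaged over dots and frames."""
    step = np.diff(seq.positions, axis=0)
    return float(np.linalg.norm(step, axis=2).mean())


# ---------------------------------------------------------------------------
# Parametric gait model
# ---------------------------------------------------------------------------

# Static skeleton offsets from body center (x, y), pixels, y down.
_BASE = {
    "head": (0.0, -160.0),
    "thorax": (0.0, -95.0),
    "pelvis": (0.0, -10.0),
    "l_shoulder": (-38.0, -105.0),
    "r_shoulder": (38.0, -105.0),
    "l_elbow": (-52.0, -55.0),
    "r_elbow": (52.0, -55.0),
    "l_wrist": (-56.0, -5.0),
    "r_wrist": (56.0, -5.0),
    "l_hip": (-20.0, 0.0),
    "r_hip": (20.0, 0.0),
    "l_knee": (-23.0, 75.0),
    "r_knee": (23.0, 75.0),
    "l_ankle": (-26.0, 155.0),
    "r_ankle": (26.0, 155.0),
}

# Per-marker horizontal swing amplitude at neutral (px) and gait phase
# offset: right leg leads at phase 0, left leg (and right arm) at phase pi.
_SWING = {
    "head": (2.0, 0.0),
    "thorax": (3.0, 0.0),
    "pelvis": (4.0, 0.0),
    "l_shoulder": (5.0, 0.0),
    "r_shoulder": (5.0, math.pi),
    "l_elbow": (18.0, 0.0),
    "r_elbow": (18.0, math.pi),
    "l_wrist": (30.0, 0.0),
    "r_wrist": (30.0, math.pi),
    "l_hip": (8.0, math.pi),
    "r_hip": (8.0, 0.0),
    "l_knee": (27.0, math.pi),
    "r_knee": (27.0, 0.0),
    "l_ankle": (42.0, math.pi),
    "r_ankle": (42.0, 0.0),
}

# Vertical bounce amplitude (px) at twice the gait frequency (both feet
# strike once per cycle), plus per-leg vertical lift for the ankles.
_BOUNCE = {
    "head": 7.0,
    "thorax": 7.0,
    "pelvis": 8.0,
    "l_shoulder": 7.0,
    "r_shoulder": 7.0,
    "l_elbow": 6.0,
    "r_elbow": 6.0,
    "l_wrist": 6.0,
    "r_wrist": 6.0,
    "l_hip": 8.0,
    "r_hip": 8.0,
    "l_knee": 6.0,
    "r_knee": 6.0,
    "l_ankle": 5.0,
    "r_ankle": 5.0,
}
_ANKLE_LIFT = 12.0  # px, once per stride for each foot

# Posture droop weights (applied downward for sad walkers).
_DROOP = {
    "head": 1.0,
    "thorax": 0.5,
    "l_shoulder": 0.65,
    "r_shoulder": 0.65,
    "l_elbow": 0.3,
    "r_elbow": 0.3,
    "l_wrist": 0.15,
    "r_wrist": 0.15,
}


def _synthesize(u: float, freq: float, phase0: float, n_frames: int,
                frame_rate: float, center: tuple[float, float]) -> np.ndarray:
    """Raw gait synthesis at normalized emotion u = emotion_score / 6."""
    t = np.arange(n_frames) / frame_rate
    theta = 2.0 * math.pi * (freq * t + phase0)
    amp_scale = 1.0 + 0.35 * u           # happy: larger swing; sad: smaller
    droop = 20.0 * max(0.0, -u)          # sad: head/shoulders sink
    slump = 8.0 * max(0.0, -u)           # sad: slight forward slump (x shift)

    pos = np.empty((n_frames, len(MARKER_LABELS), 2))
    for m, label in enumerate(MARKER_LABELS):
        bx, by = _BASE[label]
        a, ph = _SWING[label]
        a *= amp_scale
        # fundamental + first overtone on x; overtone sharpens the swing
        x = bx + a * np.sin(theta + ph) + 0.25 * a * np.sin(2.0 * (theta + ph))
        y = by + _BOUNCE[label] * amp_scale * np.cos(2.0 * theta)
        if label.endswith("ankle"):
            y = y - _ANKLE_LIFT * amp_scale * np.clip(np.sin(theta + ph + math.pi / 2), 0.0, None)
        w = _DROOP.get(label, 0.0)
        y = y + droop * w
        x = x + slump * w
        pos[:, m, 0] = center[0] + x
        pos[:, m, 1] = center[1] + y
    return pos


def generate_walker(config: WalkerConfig, seed: int = 0) -> PointLightSequence:
    """Generate an emotional point-light walker.

    The seed only randomizes the initial gait phase, so repeated calls
    with the same (config, seed) are bit-identical.  The gait frequency
    is calibrated by fixed-point iteration until the mean per-dot speed
    matches ``config.resolved_speed`` to well within 1%.
    """
    rng = np.random.default_rng(seed)
    phase0 = float(rng.uniform(0.0, 1.0))
    u = config.emotion_score / 6.0
    x0, y0, x1, y1 = config.display_box
    center = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    freq = 1.0 * (1.0 + 0.25 * u)  # Hz, pre-calibration cadence
    target = config.resolved_speed
    pos = _synthesize(u, freq, phase0, config.n_frames, config.frame_rate, center)
    for _ in range(60):
        speed = float(np.linalg.norm(np.diff(pos, axis=0), axis=2).mean())
        if abs(speed - target) <= 1e-6 * target:
            break
        freq *= target / speed
        pos = _synthesize(u, freq, phase0, config.n_frames, config.frame_rate, center)

    # Snap to a 2**-16 px sub-pixel grid: with positions and transform
    # offsets on a common dyadic lattice, translation (scramble) and
    # reflection (invert) are exact in float64, so frame-difference
    # vectors and involution identities hold bit-for-bit.
    pos = np.round(pos * 65536.0) / 65536.0
    if config.direction == "left45":
        pos[:, :, 0] = (x0 + x1) - pos[:, :, 0]
    return PointLightSequence(
        positions=pos, frame_rate=config.frame_rate, display_box=config.display_box
    )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def invert(seq: PointLightSequence) -> PointLightSequence:
    """Mirror-flip the walker vertically about the display box midline.

    If the sequence carries no display box the bounding-box midline is
    used; either choice makes the operation an exact involution.
    """
    if seq.display_box is not None:
        _, y0, _, y1 = seq.display_box
    else:
        _, y0, _, y1 = seq.bounding_box()
    y_mid = (y0 + y1) / 2.0
    pos = seq.positions.copy()
    pos[:, :, 1] = 2.0 * y_mid - pos[:, :, 1]
    return replace(seq, positions=pos)


def scramble(seq: PointLightSequence, seed: int) -> PointLightSequence:
    """Spatially scramble the walker while preserving local motion.

    Each dot's whole trajectory is rigidly translated so its first-frame
    position is uniform over the bounding box of the original sequence.
    Frame-to-frame displacement vectors are bit-identical to the input's.
    """
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = seq.bounding_box()
    n_markers = seq.positions.shape[1]
    new0 = np.column_stack(
        [rng.uniform(x0, x1, n_markers), rng.uniform(y0, y1, n_markers)]
    )
    # Quantize the translation to the same 2**-16 px lattice the
    # generator uses; on that lattice the rigid shift is exact in
    # float64 and frame-difference vectors are preserved bit-for-bit.
    offset = np.round((new0 - seq.positions[0]) * 65536.0) / 65536.0
    return replace(seq, positions=seq.positions + offset[None, :, :])


def remove_acceleration(seq: PointLightSequence) -> PointLightSequence:
    """Reparameterize each dot to constant speed along its original path.

    Every dot keeps its trajectory (the piecewise-linear path through
    its frame positions) but travels it at constant speed equal to its
    average speed: the arc length covered per frame becomes
    total path length / (n_frames - 1), so per-dot mean speed and path
    length are conserved and the endpoints are untouched.  Dots with a
    degenerate (zero-length) path pass through unchanged.
    """
    pos = seq.positions
    n_frames, n_markers, _ = pos.shape
    out = pos.copy()
    for m in range(n_markers):
        p = pos[:, m, :]
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        total = seg.sum()
        if total <= 0.0:
            continue
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.linspace(0.0, total, n_frames)
        out[:, m, 0] = np.interp(s, arc, p[:, 0])
        out[:, m, 1] = np.interp(s, arc, p[:, 1])
        out[0, m] = p[0]
        out[-1, m] = p[-1]
    return replace(seq, positions=out)


def path_arc_positions(path_points: np.ndarray, query_points: np.ndarray) -> np.ndarray:
    """Arc-length coordinate of each query point along a polyline.

    Projects each query point onto the polyline through ``path_points``
    and returns its distance along the path, constrained to be monotone
    non-decreasing so that self-overlapping paths (oscillating dots
    traverse nearly the same line repeatedly) resolve to the correct
    pass.  Used to verify constant-speed traversal of a dot's original
    trajectory.
    """
    p = np.asarray(path_points, dtype=float)
    q = np.asarray(query_points, dtype=float)
    seg = np.diff(p, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arc0 = np.concatenate([[0.0], np.cumsum(seglen)])
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_l2 = np.where(seglen > 0, 1.0 / np.maximum(seglen, 1e-300) ** 2, 0.0)
    out = np.empty(q.shape[0])
    s_prev = 0.0
    for i, pt in enumerate(q):
        tpar = np.clip(np.einsum("ij,ij->i", pt - p[:-1], seg) * inv_l2, 0.0, 1.0)
        proj = p[:-1] + tpar[:, None] * seg
        d2 = np.einsum("ij,ij->i", pt - proj, pt - proj)
        s = arc0[:-1] + tpar * seglen
        ok = s >= s_prev - 1e-9
        if not ok.any():
            ok = np.ones_like(ok, dtype=bool)
        d2 = np.where(ok, d2, np.inf)
        j = int(np.argmin(d2))
        s_prev = float(s[j])
        out[i] = s_prev
    return out


# ---------------------------------------------------------------------------
# Frame-table I/O
# ---------------------------------------------------------------------------

def write_frame_table(seq: PointLightSequence, path) -> None:
    """Write a sequence as a TSV frame table (frame, marker_label, x, y)."""
    n_frames, n_markers, _ = seq.positions.shape
    frame = np.repeat(np.arange(n_frames), n_markers)
    labels = list(seq.marker_labels) * n_frames
    flat = seq.positions.reshape(-1, 2)
    df = pd.DataFrame(
        {"frame": frame, "marker_label": labels, "x": flat[:, 0], "y": flat[:, 1]}
    )
    with open(path, "w") as fh:
        fh.write(f"# frame_rate: {seq.frame_rate!r}\n")
        if seq.display_box is not None:
            fh.write("# display_box: %r %r %r %r\n" % tuple(seq.display_box))
        df.to_csv(fh, sep="\t", index=False)


def read_frame_table(path) -> PointLightSequence:
    """Read a sequence written by :func:`write_frame_table`."""
    frame_rate = 60.0
    display_box = None
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, val = line[1:].partition(":")
            key = key.strip()
            if key == "frame_rate":
                frame_rate = float(val)
            elif key == "display_box":
                display_box = tuple(float(v) for v in val.split())
    df = pd.read_csv(path, sep="\t", comment="#")
    labels = tuple(df["marker_label"].iloc[: df["frame"].eq(0).sum()])
    n_frames = int(df["frame"].max()) + 1
    pos = df[["x", "y"]].to_numpy().reshape(n_frames, len(labels), 2)
    return PointLightSequence(
        positions=pos,
        frame_rate=frame_rate,
        marker_labels=labels,
        display_box=display_box,
    )
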