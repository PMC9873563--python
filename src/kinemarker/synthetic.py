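"""Synthetic motion-capture cohorts with known ground truth.

The clinical recordings this package was designed around are not public, so
every downstream test runs on simulated data with the same statistical
structure: two groups (patients / controls) whose full-body gait and peg-test
kinematics differ in cycle-duration jitter, tremor, postural sway, joint
power, inter-joint coupling and movement speed — all monotone in a latent
severity in [0, 1] — plus clinical labels (SARA-like 0–40, SCAFI-like
continuous, an FXN-like normalized-Ct molecular level) generated as noisy
monotone functions of that severity.

The generator is first-class, tested code: it defines the study conditions
(group sizes, visit schedule, noise levels, label model) and exposes the
ground truth (stride boundaries, latent severities, noiseless labels) that
the segmentation, feature and modeling tests recover.

Gait waveforms are per-joint Fourier templates (2 harmonics, joint-specific
amplitude and phase, arm swing antiphase to the ipsilateral leg, hip flexion
~±25 deg, knee flexion ~0–60 deg, cycle ~1.15 s) driven by a common cycle
clock; peg-test reaches follow minimum-jerk-like out-and-back profiles.  They
are plausible, not biomechanically validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .skeleton_io import (EndSite, Joint, KinematicsBundle, MotionRecording,
                          SkeletonModel, compute_kinematics, write_bvh)

__all__ = [
    "suit_skeleton",
    "NoiseModel",
    "LabelModel",
    "SyntheticCohortSpec",
    "RecordingTruth",
    "SyntheticCohort",
    "simulate_gait_recording",
    "simulate_pegtest_recording",
    "simulate_cohort",
    "simulate_labels",
    "write_bvh",
]

_ROT = "ZXY"  # channel order used by the suit template


def suit_skeleton() -> SkeletonModel:
    """The 17-joint / 51-DoF suit hierarchy with 26 tracked segments.

    Offsets are rest-pose cm for an average adult; 9 end sites (head top,
    hands, toes, sacrum, sternum and both acromion markers) bring the tracked
    segment count to 26 (78 position DoF).
    """
    J = Joint
    joints = (
        J("Hips", -1, (0.0, 100.0, 0.0), _ROT, has_translation=True),
        J("Spine", 0, (0.0, 12.0, 0.0), _ROT),
        J("Chest", 1, (0.0, 18.0, 0.0), _ROT),
        J("Neck", 2, (0.0, 22.0, 0.0), _ROT),
        J("Head", 3, (0.0, 10.0, 0.0), _ROT),
        J("LeftShoulder", 2, (20.0, 16.0, 0.0), _ROT),
        J("LeftElbow", 5, (28.0, 0.0, 0.0), _ROT),
        J("LeftWrist", 6, (25.0, 0.0, 0.0), _ROT),
        J("RightShoulder", 2, (-20.0, 16.0, 0.0), _ROT),
        J("RightElbow", 8, (-28.0, 0.0, 0.0), _ROT),
        J("RightWrist", 9, (-25.0, 0.0, 0.0), _ROT),
        J("LeftHip", 0, (9.0, -4.0, 0.0), _ROT),
        J("LeftKnee", 11, (0.0, -42.0, 0.0), _ROT),
        J("LeftAnkle", 12, (0.0, -40.0, 0.0), _ROT),
        J("RightHip", 0, (-9.0, -4.0, 0.0), _ROT),
        J("RightKnee", 14, (0.0, -42.0, 0.0), _ROT),
        J("RightAnkle", 15, (0.0, -40.0, 0.0), _ROT),
    )
    name = {j.name: i for i, j in enumerate(joints)}
    ends = (
        EndSite(name["Head"], (0.0, 18.0, 0.0)),
        EndSite(name["LeftWrist"], (16.0, 0.0, 0.0)),
        EndSite(name["RightWrist"], (-16.0, 0.0, 0.0)),
        EndSite(name["LeftAnkle"], (0.0, -8.0, 14.0)),
        EndSite(name["RightAnkle"], (0.0, -8.0, 14.0)),
        EndSite(name["Hips"], (0.0, -2.0, -10.0)),
        EndSite(name["Chest"], (0.0, 5.0, 10.0)),
        EndSite(name["LeftShoulder"], (6.0, 6.0, 0.0)),
        EndSite(name["RightShoulder"], (-6.0, 6.0, 0.0)),
    )
    return SkeletonModel(joints=joints, end_sites=ends)


# ---------------------------------------------------------------------------
# Generative parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Severity-dependent disturbance magnitudes, each ``base + slope*severity``.

    Units: cycle_jitter as a fraction of the cycle duration; tremor in deg
    (added to every angular channel after 8 Hz smoothing); sway in deg on the
    trunk/head channels; power_loss and speed_loss as fractional reductions of
    joint amplitude and walking speed; decoupling in cycles of per-channel
    phase wander.
    """

    cycle_jitter: tuple[float, float] = (0.012, 0.08)
    tremor: tuple[float, float] = (0.12, 0.45)
    sway: tuple[float, float] = (0.4, 5.0)
    power_loss: tuple[float, float] = (0.0, 0.32)
    decoupling: tuple[float, float] = (0.004, 0.05)
    speed_loss: tuple[float, float] = (0.0, 0.38)

    def at(self, severity: float) -> dict[str, float]:
        out = {}
        for name in ("cycle_jitter", "tremor", "sway", "power_loss",
                     "decoupling", "speed_loss"):
            base, slope = getattr(self, name)
            if base < 0 or base + slope < 0:
                raise ValueError(f"noise magnitude {name} must stay non-negative")
            out[name] = base + slope * severity
        return out


@dataclass(frozen=True)
class LabelModel:
    """Severity -> (SARA, SCAFI, FXN) with Gaussian noise.

    Defaults span the study's reported ranges: SARA = 4 + 28*severity
    (clipped to [0, 40], noise sd 1.5), SCAFI = 1.4 - 2.5*severity (sd 0.15),
    FXN normalized Ct = 5 + 2*severity_trait (sd 0.3) where severity_trait is
    the subject's time-invariant baseline latent — FXN expression does not
    track short-term kinematic change.
    """

    sara: tuple[float, float, float] = (4.0, 28.0, 1.5)
    scafi: tuple[float, float, float] = (1.4, -2.5, 0.15)
    fxn: tuple[float, float, float] = (5.0, 2.0, 0.3)

    def __post_init__(self):
        for name in ("sara", "scafi", "fxn"):
            if getattr(self, name)[2] < 0:
                raise ValueError(f"{name} noise sd must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative description of a study cohort.

    Visit times default to the study schedule (baseline, 3 weeks, 3 and 9
    months); controls are seen once at baseline.  ``severity0`` names the
    baseline-severity distribution of patients (controls are fixed at 0);
    ``progression_rate`` is per-month latent drift.
    """

    n_patients: int = 9
    n_controls: int = 9
    visits_months: tuple[float, ...] = (0.0, 0.75, 3.0, 9.0)
    control_visits_months: tuple[float, ...] = (0.0,)
    severity0: tuple[str, float, float] = ("beta", 1.6, 3.2)
    progression_rate: float = 0.007
    noise: NoiseModel = field(default_factory=NoiseModel)
    label_model: LabelModel = field(default_factory=LabelModel)
    n_repeats: int = 2
    n_peg_cycles: int = 9
    frame_rate: float = 60.0
    walk_distance_cm: float = 800.0
    seed: int = 0

    def draw_severity0(self, rng: np.random.Generator, n: int) -> np.ndarray:
        kind, a, b = self.severity0
        if kind == "beta":
            return rng.beta(a, b, size=n)
        if kind == "uniform":
            return rng.uniform(a, b, size=n)
        raise ValueError(f"unknown severity0 distribution {kind!r}")


@dataclass(frozen=True)
class RecordingTruth:
    """Per-recording ground truth for downstream oracles."""

    severity: float
    stride_boundaries: np.ndarray | None = None
    mean_cycle_s: float | None = None
    place_events: np.ndarray | None = None

    def __post_init__(self):
        if self.stride_boundaries is not None:
            b = np.asarray(self.stride_boundaries)
            if b.size and np.any(np.diff(b) <= 0):
                raise ValueError("stride boundaries must be strictly increasing")


# ---------------------------------------------------------------------------
# Gait templates
# ---------------------------------------------------------------------------

# joint -> axis -> (offset_deg, [(harmonic, amplitude_deg, phase_rad), ...])
# phases are relative to the ipsilateral leg's cycle clock
_GAIT_TEMPLATE = {
    "Hips": {"X": (2.0, [(2, 3.0, 0.0)]), "Z": (0.0, [(1, 4.0, 1.3)]),
             "Y": (0.0, [(1, 7.0, 0.0)])},
    "Spine": {"X": (3.0, [(2, 2.5, 0.7)]), "Z": (0.0, [(1, 2.5, 2.0)]),
              "Y": (0.0, [(1, 4.0, 3.14)])},
    "Chest": {"X": (2.0, [(2, 2.0, 1.1)]), "Z": (0.0, [(1, 2.0, 2.4)]),
              "Y": (0.0, [(1, 3.5, 3.14)])},
    "Neck": {"X": (-2.0, [(2, 1.8, 0.4)]), "Z": (0.0, [(1, 1.5, 1.7)]),
             "Y": (0.0, [(1, 2.0, 0.5)])},
    "Head": {"X": (0.0, [(2, 1.5, 0.9)]), "Z": (0.0, [(1, 1.2, 2.2)]),
             "Y": (0.0, [(1, 1.5, 0.2)])},
    "Hip": {"X": (0.0, [(1, 25.0, 0.0), (2, 5.0, 0.6)]),
            "Z": (0.0, [(1, 6.0, 1.57)]), "Y": (0.0, [(1, 8.0, 0.79)])},
    "Knee": {"X": (30.0, [(1, 30.0, -1.57), (2, 10.0, 0.3)]),
             "Z": (0.0, [(1, 4.0, 0.9)]), "Y": (0.0, [(1, 5.0, 1.9)])},
    "Ankle": {"X": (0.0, [(1, 15.0, 0.5), (2, 6.0, 1.2)]),
              "Z": (0.0, [(1, 4.0, 2.1)]), "Y": (0.0, [(1, 4.0, 0.3)])},
    "Shoulder": {"X": (5.0, [(1, 15.0, 3.14)]), "Z": (8.0, [(1, 5.0, 2.3)]),
                 "Y": (0.0, [(1, 5.0, 1.0)])},
    "Elbow": {"X": (20.0, [(1, 10.0, 3.14), (2, 3.0, 0.8)]),
              "Z": (0.0, [(1, 3.0, 2.6)]), "Y": (0.0, [(1, 3.0, 0.4)])},
    "Wrist": {"X": (0.0, [(1, 5.0, 2.9)]), "Z": (0.0, [(1, 4.0, 1.4)]),
              "Y": (0.0, [(1, 3.0, 0.6)])},
}

_SWAY_CHANNELS = ("Hips", "Spine", "Chest", "Neck", "Head")
_BASE_CYCLE_S = 1.15
_BASE_STRIDE_CM = 115.0


def _template_for(joint_name: str):
    for prefix in ("Left", "Right"):
        if joint_name.startswith(prefix):
            return _GAIT_TEMPLATE[joint_name[len(prefix):]], prefix
    return _GAIT_TEMPLATE[joint_name], None


def _smooth_noise(rng: np.random.Generator, n: int, frame_rate: float,
                  cutoff_hz: float, sd: float) -> np.ndarray:
    """Band-limited Gaussian noise with the requested marginal sd."""
    if sd <= 0:
        return np.zeros(n)
    from .feature_core import butter_lowpass, filtfilt_safe
    w = rng.standard_normal(n + 120)
    b, a = butter_lowpass(cutoff_hz, frame_rate, order=2)
    s = filtfilt_safe(b, a, w)[60:60 + n]
    s_sd = s.std()
    return s / s_sd * sd if s_sd > 0 else np.zeros(n)


def _cycle_clock(rng: np.random.Generator, duration_s: float, frame_rate: float,
                 cycle_s: float, jitter_frac: float):
    """Piecewise-linear phase phi(t) whose per-cycle durations are jittered.

    Returns (phi per frame, stride-start frame indices, realized cycle
    durations in seconds).
    """
    n = int(round(duration_s * frame_rate))
    durations = []
    total = 0.0
    while total < duration_s + cycle_s:
        d = cycle_s * max(0.3, 1.0 + jitter_frac * rng.standard_normal())
        durations.append(d)
        total += d
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    t = np.arange(n) / frame_rate
    idx = np.searchsorted(starts, t, side="right") - 1
    phi = idx + (t - starts[idx]) / np.asarray(durations)[idx]
    boundary_frames = np.ceil(starts[:-1] * frame_rate).astype(int)
    boundary_frames = boundary_frames[boundary_frames < n]
    return phi, boundary_frames, np.asarray(durations)


def simulate_gait_recording(severity: float, duration_s: float | None = None,
                            frame_rate: float = 60.0, seed: int | np.random.Generator = 0,
                            noise: NoiseModel | None = None,
                            hand_dominance: str = "right",
                            walk_distance_cm: float | None = 800.0,
                            cycle_s: float | None = None,
                            **metadata) -> tuple[MotionRecording, RecordingTruth]:
    """Simulate one 8-m-walk recording at a given latent severity.

    The 51 channels follow per-joint Fourier gait templates driven by a common
    cycle clock (per-cycle duration jittered in proportion to severity);
    severity additionally attenuates joint amplitudes, adds tremor, increases
    trunk/head sway, decouples inter-joint phases and slows the forward
    progression.  If ``duration_s`` is None, it is set to the time needed to
    cover ``walk_distance_cm`` at the severity-reduced speed (min 3 cycles).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = noise or NoiseModel()
    mags = noise.at(severity)
    if cycle_s is None:
        cycle_s = _BASE_CYCLE_S * (1.0 + 0.25 * severity)
    stride_cm = _BASE_STRIDE_CM * (1.0 - mags["speed_loss"])
    if duration_s is None:
        if walk_distance_cm is None:
            raise ValueError("give duration_s or walk_distance_cm")
        duration_s = walk_distance_cm / (stride_cm / cycle_s)
    if duration_s < 3 * cycle_s:
        raise ValueError(f"duration {duration_s:.2f}s is under 3 gait cycles")

    sk = suit_skeleton()
    phi, boundaries, durations = _cycle_clock(rng, duration_s, frame_rate,
                                              cycle_s, mags["cycle_jitter"])
    n = len(phi)
    amp_scale = 1.0 - mags["power_loss"]
    angles = np.zeros((n, sk.n_rotation_channels))
    for ji, joint in enumerate(sk.joints):
        tmpl, side = _template_for(joint.name)
        side_phase = 0.5 if side == "Right" else 0.0
        # arm swing is antiphase to the ipsilateral leg: encoded in template phases
        for ci, ax in enumerate(joint.rotation_order):
            off, harmonics = tmpl[ax]
            decouple = _smooth_noise(rng, n, frame_rate, 0.5, mags["decoupling"])
            ph = phi + side_phase + decouple
            y = np.full(n, off)
            for h, amp, phase0 in harmonics:
                y = y + amp_scale * amp * np.sin(2 * np.pi * h * ph + phase0)
            if joint.name in _SWAY_CHANNELS:
                y = y + _smooth_noise(rng, n, frame_rate, 1.2, mags["sway"])
            y = y + _smooth_noise(rng, n, frame_rate, 4.0, mags["tremor"])
            angles[:, 3 * ji + ci] = y

    trans = np.zeros((n, 3))
    trans[:, 2] = stride_cm * phi
    trans[:, 1] = 2.0 * np.sin(4 * np.pi * phi) + _smooth_noise(rng, n, frame_rate, 2.0,
                                                                0.2 + 0.5 * severity)
    trans[:, 0] = _smooth_noise(rng, n, frame_rate, 1.0, 0.8 + 3.0 * severity)

    rec = MotionRecording(skeleton=sk, angles=angles, root_translation=trans,
                          frame_rate=frame_rate, task="8MW",
                          hand_dominance=hand_dominance, **metadata)
    truth = RecordingTruth(severity=severity, stride_boundaries=boundaries,
                           mean_cycle_s=float(np.mean(durations[: max(1, len(boundaries) - 1)])))
    return rec, truth


# ---------------------------------------------------------------------------
# Peg-test generator
# ---------------------------------------------------------------------------

def _minjerk(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 10 * u ** 3 - 15 * u ** 4 + 6 * u ** 5

# task-arm reach profile: axis -> (dwell_deg, reach_amplitude_deg)
_PEG_ARM = {
    "Shoulder": {"X": (10.0, 28.0), "Z": (6.0, 12.0), "Y": (0.0, 9.0)},
    "Elbow": {"X": (45.0, -30.0), "Z": (0.0, 5.0), "Y": (5.0, 16.0)},
    "Wrist": {"X": (0.0, 12.0), "Z": (0.0, -8.0), "Y": (0.0, 6.0)},
}
_PEG_SEATED_POSE = {  # joint -> axis -> constant deg while seated
    "Hip": {"X": 80.0, "Z": 0.0, "Y": 0.0},
    "Knee": {"X": 85.0, "Z": 0.0, "Y": 0.0},
    "Ankle": {"X": 10.0, "Z": 0.0, "Y": 0.0},
}


def simulate_pegtest_recording(severity: float, hand: str = "D", n_peg_cycles: int = 9,
                               frame_rate: float = 60.0,
                               seed: int | np.random.Generator = 0,
                               noise: NoiseModel | None = None,
                               hand_dominance: str = "right",
                               lead_in_s: float = 0.6,
                               **metadata) -> tuple[MotionRecording, RecordingTruth]:
    """Simulate one 9-hole-peg-test recording (seated, one task arm).

    The task arm's shoulder/elbow/wrist channels perform ``n_peg_cycles``
    minimum-jerk-like reach–place–return cycles between a dwell pose and
    slightly scattered hole targets.  Severity lengthens the cycles (slower
    movement), adds tremor, and widens the target scatter (larger workspace);
    the non-task arm is near-static and the lower body is static (seated).
    """
    if hand not in ("D", "ND"):
        raise ValueError("hand must be 'D' or 'ND'")
    if n_peg_cycles < 1:
        raise ValueError("n_peg_cycles must be >= 1")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = noise or NoiseModel()
    mags = noise.at(severity)

    task_side = ("Right" if hand_dominance == "right" else "Left") if hand == "D" else \
        ("Left" if hand_dominance == "right" else "Right")
    cycle_s = 1.9 * (1.0 + 1.2 * severity)
    durations = cycle_s * np.maximum(0.4, 1.0 + (0.04 + 0.10 * severity)
                                     * rng.standard_normal(n_peg_cycles))
    starts = lead_in_s + np.concatenate([[0.0], np.cumsum(durations)])
    duration_s = starts[-1] + 0.4
    n = int(round(duration_s * frame_rate))
    t = np.arange(n) / frame_rate

    # per-peg amplitude scatter: severity widens the visited workspace
    scatter = 0.06 + 0.38 * severity
    peg_scale = 1.0 + scatter * rng.standard_normal(n_peg_cycles)

    # reach profile w(t): 0 at dwell, 1 at the hole, minimum-jerk both ways
    w = np.zeros(n)
    place_frames = []
    for k in range(n_peg_cycles):
        a, b = starts[k], starts[k] + durations[k]
        m = (t >= a) & (t < b)
        p = (t[m] - a) / durations[k]
        prof = np.where(p <= 0.5, _minjerk(2 * p), _minjerk(2 * (1 - p)))
        w[m] = peg_scale[k] * prof
        place_frames.append(int(round((a + durations[k] / 2) * frame_rate)))

    sk = suit_skeleton()
    angles = np.zeros((n, sk.n_rotation_channels))
    for ji, joint in enumerate(sk.joints):
        name = joint.name
        for ci, ax in enumerate(joint.rotation_order):
            val = np.zeros(n)
            if name.startswith(("Left", "Right")):
                side, base_name = (name[:5], name[5:]) if name.startswith("Right") else (name[:4], name[4:])
                if base_name in _PEG_ARM:
                    dwell, amp = _PEG_ARM[base_name][ax]
                    if side == task_side:
                        val = dwell + amp * w + _smooth_noise(rng, n, frame_rate, 4.0,
                                                              mags["tremor"])
                    else:
                        val = np.full(n, dwell * 0.6)  # resting on the lap
                elif base_name in _PEG_SEATED_POSE:
                    val = np.full(n, _PEG_SEATED_POSE[base_name][ax])
            else:
                # trunk/head: postural sway only, growing with severity
                val = _smooth_noise(rng, n, frame_rate, 1.0, 0.12 * mags["sway"]) \
                    + _smooth_noise(rng, n, frame_rate, 4.0, 0.25 * mags["tremor"])
            angles[:, 3 * ji + ci] = val

    trans = np.zeros((n, 3))
    trans[:, 1] = -45.0  # seated pelvis height drop
    rec = MotionRecording(skeleton=sk, angles=angles, root_translation=trans,
                          frame_rate=frame_rate, task=f"9HPT-{hand}",
                          hand_dominance=hand_dominance, **metadata)
    truth = RecordingTruth(severity=severity,
                           place_events=np.asarray(place_frames, dtype=int))
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """All simulated recordings of a cohort plus labels and ground truth.

    ``recordings`` maps (subject_id, visit_id, task, repeat) to the
    MotionRecording (task in {"8MW", "9HPT-D", "9HPT-ND"}); ``labels`` has one
    row per subject-visit; ``truth`` maps recording keys to
    :class:`RecordingTruth` and ``noiseless_labels`` mirrors ``labels``
    without observation noise.
    """

    spec: SyntheticCohortSpec
    recordings: dict[tuple, MotionRecording]
    labels: pd.DataFrame
    truth: dict[tuple, RecordingTruth]
    noiseless_labels: pd.DataFrame

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(k[0] for k in self.recordings))


def _subject_visits(spec: SyntheticCohortSpec):
    """Yield (subject_id, group, visit_id, months) in deterministic order."""
    for p in range(spec.n_patients):
        sid = f"P{p + 1:02d}"
        for vi, months in enumerate(spec.visits_months):
            yield sid, "patient", f"V{vi + 1}", months
    for c in range(spec.n_controls):
        sid = f"C{c + 1:02d}"
        for vi, months in enumerate(spec.control_visits_months):
            yield sid, "control", f"V{vi + 1}", months


def simulate_labels(spec: SyntheticCohortSpec, severity_table: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw noisy and noiseless labels for a table of subject-visit severities.

    ``severity_table`` must hold columns subject_id, visit_id, group, months,
    severity and severity_trait (the baseline latent driving FXN).  Controls
    get NaN FXN (no molecular sample in the study design).
    """
    lm = spec.label_model
    sev = severity_table["severity"].to_numpy()
    trait = severity_table["severity_trait"].to_numpy()
    is_patient = (severity_table["group"] == "patient").to_numpy()

    def lin(params, x):
        a, b, _ = params
        return a + b * x

    clean = severity_table[["subject_id", "visit_id", "group", "months"]].copy()
    clean["SARA"] = np.clip(lin(lm.sara, sev), 0.0, 40.0)
    clean["SCAFI"] = lin(lm.scafi, sev)
    clean["FXN"] = np.where(is_patient, lin(lm.fxn, trait), np.nan)

    noisy = clean.copy()
    n = len(clean)
    noisy["SARA"] = np.clip(clean["SARA"] + lm.sara[2] * rng.standard_normal(n), 0.0, 40.0)
    noisy["SCAFI"] = clean["SCAFI"] + lm.scafi[2] * rng.standard_normal(n)
    fxn_noise = lm.fxn[2] * rng.standard_normal(n)
    noisy["FXN"] = clean["FXN"] + np.where(is_patient, fxn_noise, 0.0)
    return noisy, clean


def simulate_cohort(spec: SyntheticCohortSpec,
                    tasks: tuple[str, ...] = ("8MW", "9HPT")) -> SyntheticCohort:
    """Simulate a full cohort: recordings, labels and ground truth.

    Per subject-visit: ``n_repeats`` 8-MW recordings and ``n_repeats`` 9-HPT
    recordings per hand (the protocol repeats each task twice), all at the
    visit's latent severity ``severity0 + progression_rate * months`` (clipped
    to [0, 1]); labels from the label model.  Identical spec + seed give a
    bit-identical cohort; kinematics and labels use independent random
    streams so the label noise can be re-drawn without changing recordings.
    """
    if spec.n_patients < 1 or spec.n_controls < 1:
        raise ValueError("both groups must be nonempty")
    ss = np.random.SeedSequence(spec.seed)
    ss_subj, ss_kin, ss_labels = ss.spawn(3)
    rng_subj = np.random.default_rng(ss_subj)

    sev0 = np.clip(spec.draw_severity0(rng_subj, spec.n_patients), 0.0, 1.0)
    dominance = {}
    for sid in [f"P{i + 1:02d}" for i in range(spec.n_patients)] + \
               [f"C{i + 1:02d}" for i in range(spec.n_controls)]:
        dominance[sid] = "right" if rng_subj.random() < 0.9 else "left"

    rows = []
    for sid, group, vid, months in _subject_visits(spec):
        trait = sev0[int(sid[1:]) - 1] if group == "patient" else 0.0
        sev = float(np.clip(trait + spec.progression_rate * months, 0.0, 1.0)) \
            if group == "patient" else 0.0
        rows.append(dict(subject_id=sid, visit_id=vid, group=group, months=months,
                         severity=sev, severity_trait=float(trait)))
    sev_table = pd.DataFrame(rows)

    recordings: dict[tuple, MotionRecording] = {}
    truth: dict[tuple, RecordingTruth] = {}
    kin_children = ss_kin.spawn(len(sev_table))
    for (_, row), child in zip(sev_table.iterrows(), kin_children):
        rng = np.random.default_rng(child)
        sid, vid = row["subject_id"], row["visit_id"]
        meta = dict(subject_id=sid, visit_id=vid, group=row["group"])
        dom = dominance[sid]
        if "8MW" in tasks:
            for rep in range(1, spec.n_repeats + 1):
                rec, tr = simulate_gait_recording(
                    row["severity"], frame_rate=spec.frame_rate, seed=rng,
                    noise=spec.noise, hand_dominance=dom,
                    walk_distance_cm=spec.walk_distance_cm, **meta)
                recordings[(sid, vid, "8MW", rep)] = rec
                truth[(sid, vid, "8MW", rep)] = tr
        if "9HPT" in tasks:
            for hand in ("D", "ND"):
                for rep in range(1, spec.n_repeats + 1):
                    rec, tr = simulate_pegtest_recording(
                        row["severity"], hand=hand, n_peg_cycles=spec.n_peg_cycles,
                        frame_rate=spec.frame_rate, seed=rng, noise=spec.noise,
                        hand_dominance=dom, **meta)
                    recordings[(sid, vid, f"9HPT-{hand}", rep)] = rec
                    truth[(sid, vid, f"9HPT-{hand}", rep)] = tr

    labels, clean = simulate_labels(spec, sev_table, np.random.default_rng(ss_labels))
    labels = labels.merge(sev_table[["subject_id", "visit_id", "severity",
                                     "severity_trait"]],
                          on=["subject_id", "visit_id"])
    return SyntheticCohort(spec=spec, recordings=recordings, labels=labels,
                           truth=truth, noiseless_labels=clean)
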