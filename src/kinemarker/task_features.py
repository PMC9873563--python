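"""Task-level feature vectors: the 8-MW gait set (F1–F9, 31 scalars) and the
9-HPT upper-body set (F10–F18, 33 scalars).

Each family is a named group of scalars assembled from the primitives in
:mod:`kinemarker.feature_core`:

========  ===============================================================
family    content (count)
========  ===============================================================
F1        trunk-referenced workspace volume + entropy (2)
F2        cycle-normalized hip / knee velocity variability (2)
F3        autocorrelation PC1/PC2 value at the first walk cycle (2)
F4        channel-delay cross-correlation eigenvalues at ranks 1, 5, 35 (3)
F5        dominant / non-dominant ankle mean per-stride peak speed (2)
F6        walk complexity % + PCs needed for 90% variance (2)
F7        per-cycle spectral energy of 6 leg channels (6)
F8        9 Pearson correlations between D and ND leg velocities (9)
F9        head-plane hull area + frontal / sideways sd (3)
F10       mean |angular velocity| of 5 task-arm channels (5)
F11       upper-body complexity % + PCs for 90% (2)
F12       upper-body workspace volume + entropy (2)
F13       autocorrelation FWHM of 5 task-arm channels (5)
F14       delay cross-correlation eigenvalues at ranks 1, 5, 30, 300 (4)
F15       mean spectral RMS power of 5 task-arm channels (5)
F16       wrist mean speed (1)
F17       logistic scale of 7 upper-body velocity channels + wrist speed (8)
F18       head-plane hull area (1)
========  ===============================================================

Features that exist per hand (the peg test is performed with each hand) are
computed per hand and averaged, so each family keeps a single set of values
per visit-repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import feature_core as fc
from .segmentation import StrideSegmentation, detect_strides, time_normalize_cycles
from .skeleton_io import KinematicsBundle, compute_kinematics

__all__ = [
    "FeatureVector",
    "CohortTable",
    "FeatureExtractionError",
    "GAIT_FEATURE_NAMES",
    "UPPERBODY_FEATURE_NAMES",
    "extract_gait_features",
    "extract_upperbody_features",
    "extract_cohort_features",
    "build_feature_table",
    "test_retest_correlation",
    "group_difference_screen",
    "paired_hand_test",
]


class FeatureExtractionError(RuntimeError):
    """An upstream failure, annotated with the feature family it broke."""


_ARM_CHANNELS = (  # (joint suffix, axis label, short name)
    ("Shoulder", "flexion", "shoulder_flexion"),
    ("Shoulder", "abduction", "shoulder_abduction"),
    ("Shoulder", "rotation", "shoulder_rotation"),
    ("Elbow", "flexion", "elbow_flexion"),
    ("Elbow", "rotation", "elbow_rotation"),
)
_TRUNK_F17 = (("Chest", "flexion", "chest_flexion"), ("Neck", "flexion", "neck_flexion"))

_F8_D = (("Hip", "flexion"), ("Hip", "abduction"), ("Knee", "flexion"))
_F8_ND = _F8_D

GAIT_FEATURE_NAMES: tuple[str, ...] = (
    "F1:volume", "F1:entropy",
    "F2:hip_variability", "F2:knee_variability",
    "F3:pc1_cycle1", "F3:pc2_cycle1",
    "F4:eig1", "F4:eig5", "F4:eig35",
    "F5:ankle_peak_speed_D", "F5:ankle_peak_speed_ND",
    "F6:complexity_pct", "F6:n_pcs_90",
    "F7:energy_hip_flexion_D", "F7:energy_hip_abduction_D", "F7:energy_knee_flexion_D",
    "F7:energy_hip_flexion_ND", "F7:energy_hip_abduction_ND", "F7:energy_knee_flexion_ND",
) + tuple(
    f"F8:{a}_{ax_a}_D__{b}_{ax_b}_ND"
    for a, ax_a in _F8_D for b, ax_b in _F8_ND
    for a, ax_a, b, ax_b in [(a.lower(), ax_a, b.lower(), ax_b)]
) + (
    "F9:head_area", "F9:head_frontal_sd", "F9:head_sideways_sd",
)

UPPERBODY_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"F10:speed_{short}" for *_, short in _ARM_CHANNELS
) + (
    "F11:complexity_pct", "F11:n_pcs_90",
    "F12:volume", "F12:entropy",
) + tuple(
    f"F13:fwhm_{short}" for *_, short in _ARM_CHANNELS
) + (
    "F14:eig1", "F14:eig5", "F14:eig30", "F14:eig300",
) + tuple(
    f"F15:power_{short}" for *_, short in _ARM_CHANNELS
) + (
    "F16:wrist_speed",
) + tuple(
    f"F17:sigma_{short}" for *_, short in _ARM_CHANNELS + _TRUNK_F17
) + (
    "F17:sigma_wrist_speed",
    "F18:head_area",
)

assert len(GAIT_FEATURE_NAMES) == 31
assert len(UPPERBODY_FEATURE_NAMES) == 33


@dataclass
class FeatureVector:
    """Ordered named scalars of one task recording (or visit-repeat)."""

    task: str  # "8MW" or "9HPT"
    values: dict[str, float]
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        expected = GAIT_FEATURE_NAMES if self.task == "8MW" else UPPERBODY_FEATURE_NAMES
        if tuple(self.values) != expected:
            raise ValueError(f"feature names/order do not match the {self.task} contract")
        if not self.flags:
            bad = [k for k, v in self.values.items() if not np.isfinite(v)]
            if bad:
                raise ValueError(f"non-finite features without a degeneracy flag: {bad}")

    def as_series(self) -> pd.Series:
        return pd.Series({f"{self.task}:{k}": v for k, v in self.values.items()})


def _family_guard(family: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise FeatureExtractionError(f"{family}: {exc}") from exc
        return wrapper
    return deco


def _side_joint(cm, base: str, side: str) -> str:
    """Resolve e.g. ('Hip', 'dominant') to the canonical joint name."""
    for prefix in ("Left", "Right"):
        name = f"{prefix}{base}"
        idx = cm.select(joints=name, side=side)
        if idx.size:
            return name
    raise KeyError(f"no {side} {base} joint in channel map")


def _world_speed(kin: KinematicsBundle, segment_index: int) -> np.ndarray:
    pos = kin.segment_positions[:, segment_index]
    vel = np.gradient(pos, 1.0 / kin.frame_rate, axis=0)
    return np.linalg.norm(vel, axis=1)


# ---------------------------------------------------------------------------
# 8-MW gait features
# ---------------------------------------------------------------------------

def extract_gait_features(kin: KinematicsBundle, seg: StrideSegmentation,
                          voxel_edge_cm: float = 2.0) -> FeatureVector:
    """Assemble the 31-value 8-MW feature vector from one walk recording."""
    cm = kin.channel_map
    if cm is None or kin.angular_velocity is None or kin.hip_frame_positions is None:
        raise ValueError("needs a full kinematics bundle (positions, velocities, map)")
    if seg.n_cycles < 2:
        raise FeatureExtractionError("segmentation: need at least 2 complete cycles")
    rec = kin.recording
    fr = kin.frame_rate
    vel = kin.angular_velocity
    values: dict[str, float] = {}
    flags: set[str] = set()

    @_family_guard("F1")
    def f1():
        pts = kin.hip_frame_positions.reshape(-1, 3)
        occ = fc.voxel_occupancy(pts, edge_cm=voxel_edge_cm)
        values["F1:volume"] = fc.workspace_volume(occ)
        values["F1:entropy"] = fc.workspace_entropy(occ)

    @_family_guard("F2")
    def f2():
        for base, key in (("Hip", "F2:hip_variability"), ("Knee", "F2:knee_variability")):
            per_channel = []
            for side in ("dominant", "nondominant"):
                joint = _side_joint(cm, base, side)
                for ch in cm.select(joints=joint):
                    v = vel[:, ch]
                    sd = v.std()
                    z = (v - v.mean()) / (sd if sd > 0 else 1.0)
                    mat = time_normalize_cycles(z, seg, n_points=101)
                    per_channel.append(float(mat.values.std(axis=0, ddof=0).mean()))
            values[key] = float(np.mean(per_channel))

    @_family_guard("F3")
    def f3():
        max_lag = int(np.ceil(2.0 * seg.mean_cycle_s * fr)) + 1
        curves = np.vstack([fc.autocorrelation(vel[:, c], max_lag)
                            for c in range(vel.shape[1])])
        _, _, (v1, v2), degenerate = fc.autocorr_cycle_pcs(curves, seg.mean_cycle_s, fr)
        if degenerate:
            flags.add("F3:degenerate")
        values["F3:pc1_cycle1"] = v1
        values["F3:pc2_cycle1"] = v2

    @_family_guard("F4")
    def f4():
        lags = np.unique(np.round(np.linspace(0, seg.mean_cycle_s * fr, 10)).astype(int))
        spec = fc.delay_crosscorr_spectrum(vel.T, lags)
        for rank in (1, 5, 35):
            values[f"F4:eig{rank}"] = spec.at_rank(rank)

    @_family_guard("F5")
    def f5():
        seg_names = rec.skeleton.segment_names()
        for side, key in (("dominant", "F5:ankle_peak_speed_D"),
                          ("nondominant", "F5:ankle_peak_speed_ND")):
            joint = _side_joint(cm, "Ankle", side)
            speed = _world_speed(kin, seg_names.index(joint))
            peaks = [speed[a:b].max() for a, b in zip(seg.boundaries[:-1], seg.boundaries[1:])]
            values[key] = float(np.mean(peaks))

    @_family_guard("F6")
    def f6():
        res = fc.pca_complexity(vel.T)
        values["F6:complexity_pct"] = res.complexity_pct
        values["F6:n_pcs_90"] = float(res.n_pcs_for[0.9])

    @_family_guard("F7")
    def f7():
        bounds_s = seg.boundaries_s
        for side, tag in (("dominant", "D"), ("nondominant", "ND")):
            for base, ax in (("Hip", "flexion"), ("Hip", "abduction"), ("Knee", "flexion")):
                joint = _side_joint(cm, base, side)
                ch = cm.find(joint, ax)
                t, rms = fc.stft_rms_power(vel[:, ch], fr, lowpass_hz=10.0)
                values[f"F7:energy_{base.lower()}_{ax}_{tag}"] = fc.cycle_energy(t, rms, bounds_s)

    @_family_guard("F8")
    def f8():
        d_sig = {}
        nd_sig = {}
        for base, ax in _F8_D:
            d_sig[f"{base.lower()}_{ax}"] = vel[:, cm.find(_side_joint(cm, base, "dominant"), ax)]
        for base, ax in _F8_ND:
            nd_sig[f"{base.lower()}_{ax}"] = vel[:, cm.find(_side_joint(cm, base, "nondominant"), ax)]
        for a, xa in d_sig.items():
            for b, xb in nd_sig.items():
                r = fc.pairwise_pearson({"a": xa, "b": xb})[("a", "b")]
                values[f"F8:{a}_D__{b}_ND"] = r

    @_family_guard("F9")
    def f9():
        seg_names = rec.skeleton.segment_names()
        head = kin.hip_frame_positions[:, seg_names.index("Head")]
        disp = rec.root_translation[-1] - rec.root_translation[0]
        disp[1] = 0.0
        fwd = disp / np.linalg.norm(disp) if np.linalg.norm(disp) > 1e-9 else (0.0, 0.0, 1.0)
        area, fsd, ssd, degen = fc.head_plane_area(head, forward_axis=fwd)
        if degen:
            flags.add("F9:degenerate")
        values["F9:head_area"] = area
        values["F9:head_frontal_sd"] = fsd
        values["F9:head_sideways_sd"] = ssd

    for step in (f1, f2, f3, f4, f5, f6, f7, f8, f9):
        step()
    ordered = {k: values[k] for k in GAIT_FEATURE_NAMES}
    return FeatureVector(task="8MW", values=ordered, flags=flags)


# ---------------------------------------------------------------------------
# 9-HPT upper-body features
# ---------------------------------------------------------------------------

def _task_arm_side(kin: KinematicsBundle) -> str:
    task = kin.recording.task
    if task.endswith("-D"):
        return "dominant"
    if task.endswith("-ND"):
        return "nondominant"
    raise ValueError(f"recording task {task!r} is not a one-hand peg test")


def _upper_channels(kin: KinematicsBundle, task_side: str) -> np.ndarray:
    """Trunk/head channels plus the task arm (the resting arm is excluded)."""
    cm = kin.channel_map
    trunk = cm.select(region="head/spine")
    arm = cm.select(region="upper", side=task_side)
    return np.concatenate([trunk, arm])


def _upper_segments(kin: KinematicsBundle, task_side: str) -> list[int]:
    cm = kin.channel_map
    sk = kin.recording.skeleton
    upper_joints = {cm.entries[c].joint for c in _upper_channels(kin, task_side)}
    seg_names = sk.segment_names()
    keep = []
    for i, joint in enumerate(sk.joints):
        if joint.name in upper_joints:
            keep.append(i)
    for k, e in enumerate(sk.end_sites):
        if sk.joints[e.parent].name in upper_joints:
            keep.append(sk.n_joints + k)
    assert len(keep) == len({seg_names[i] for i in keep})
    return keep


def _extract_one_hand(kin: KinematicsBundle, voxel_edge_cm: float,
                      fwhm_lag_s: float, f14_lag_step_s: float,
                      f14_window_s: float, values_out: dict, flags: set):
    cm = kin.channel_map
    fr = kin.frame_rate
    vel = kin.angular_velocity
    side = _task_arm_side(kin)
    arm_ch = {short: cm.find(_side_joint(cm, base, side), ax)
              for base, ax, short in _ARM_CHANNELS}
    upper = _upper_channels(kin, side)

    # F10 mean |angular velocity|
    for short, ch in arm_ch.items():
        values_out[f"F10:speed_{short}"] = float(np.mean(np.abs(vel[:, ch])))
    # F11 complexity on the upper-body set
    res = fc.pca_complexity(vel[:, upper].T)
    values_out["F11:complexity_pct"] = res.complexity_pct
    values_out["F11:n_pcs_90"] = float(res.n_pcs_for[0.9])
    # F12 workspace of upper-body segments (trunk-referenced)
    seg_idx = _upper_segments(kin, side)
    pts = kin.hip_frame_positions[:, seg_idx].reshape(-1, 3)
    occ = fc.voxel_occupancy(pts, edge_cm=voxel_edge_cm)
    values_out["F12:volume"] = fc.workspace_volume(occ)
    values_out["F12:entropy"] = fc.workspace_entropy(occ)
    # F13 FWHM of task-arm autocorrelations over a 10 s lag span
    max_lag = int(round(fwhm_lag_s * fr))
    for short, ch in arm_ch.items():
        curve = fc.autocorrelation(vel[:, ch], min(max_lag, vel.shape[0] - 1))
        width, saturated = fc.autocorr_fwhm(curve, fr)
        if saturated:
            flags.add(f"F13:{short}:saturated")
        values_out[f"F13:fwhm_{short}"] = width
    # F14 delay cross-correlation spectrum: lags over a 10 s window, 100 ms steps
    lags = np.round(np.arange(0.0, f14_window_s, f14_lag_step_s) * fr).astype(int)
    n_valid = vel.shape[0] - int(lags.max()) - 1
    stride = max(1, int(np.ceil(n_valid / 450)))
    spec = fc.delay_crosscorr_spectrum(vel[:, upper].T, lags, time_stride=stride)
    for rank in (1, 5, 30, 300):
        values_out[f"F14:eig{rank}"] = spec.at_rank(rank)
    # F15 mean spectral RMS power
    for short, ch in arm_ch.items():
        _, rms = fc.stft_rms_power(vel[:, ch], fr, lowpass_hz=10.0)
        values_out[f"F15:power_{short}"] = float(np.mean(rms))
    # F16 wrist mean speed (task hand, world frame)
    seg_names = kin.recording.skeleton.segment_names()
    wrist = _side_joint(cm, "Wrist", side)
    wrist_speed = _world_speed(kin, seg_names.index(wrist))
    values_out["F16:wrist_speed"] = float(np.mean(wrist_speed))
    # F17 logistic scale of 7 velocity channels + wrist speed
    for base, ax, short in _ARM_CHANNELS + _TRUNK_F17:
        joint = base if base in ("Chest", "Neck") else _side_joint(cm, base, side)
        ch = cm.find(joint, ax)
        values_out[f"F17:sigma_{short}"] = fc.fit_logistic_scale(vel[:, ch]).sigma
    values_out["F17:sigma_wrist_speed"] = fc.fit_logistic_scale(wrist_speed).sigma
    # F18 head-plane area
    head = kin.hip_frame_positions[:, seg_names.index("Head")]
    area, _, _, degen = fc.head_plane_area(head)
    if degen:
        flags.add("F18:degenerate")
    values_out["F18:head_area"] = area


def extract_upperbody_features(kin_D: KinematicsBundle | None,
                               kin_ND: KinematicsBundle | None,
                               voxel_edge_cm: float = 2.0,
                               fwhm_lag_s: float = 10.0,
                               f14_window_s: float = 10.0,
                               f14_lag_step_s: float = 0.1) -> FeatureVector:
    """Assemble the 33-value 9-HPT vector from the two per-hand recordings.

    Every family is computed per hand on the upper-body channels (trunk/head
    plus the task arm; the resting arm and the seated lower body are excluded)
    and averaged over hands.  If one hand's recording is missing the available
    hand is used alone and a completeness flag is set.
    """
    hands = [k for k in (kin_D, kin_ND) if k is not None]
    if not hands:
        raise ValueError("at least one hand's recording is required")
    flags: set[str] = set()
    if len(hands) == 1:
        flags.add("single_hand")
    per_hand = []
    for kin in hands:
        vals: dict[str, float] = {}
        try:
            _extract_one_hand(kin, voxel_edge_cm, fwhm_lag_s, f14_lag_step_s,
                              f14_window_s, vals, flags)
        except Exception as exc:  # noqa: BLE001
            raise FeatureExtractionError(f"9HPT ({kin.recording.task}): {exc}") from exc
        per_hand.append(vals)
    merged = {k: float(np.mean([v[k] for v in per_hand])) for k in UPPERBODY_FEATURE_NAMES}
    return FeatureVector(task="9HPT", values=merged, flags=flags)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Subject-visit-repeat rows joining features with labels and metadata.

    ``df`` holds one row per (subject_id, visit_id, repeat) with feature
    columns named ``"<task>:<family>:<name>"``, label columns SARA / SCAFI /
    FXN, and metadata (group, months).  The two repeats of a visit share
    labels: they are independent suit measurements of the same clinical state.
    """

    df: pd.DataFrame

    KEY = ["subject_id", "visit_id", "repeat"]
    LABELS = ["SARA", "SCAFI", "FXN"]

    def __post_init__(self):
        if self.df.duplicated(self.KEY).any():
            raise ValueError("duplicated (subject, visit, repeat) keys")

    def feature_columns(self, task: str) -> list[str]:
        return [c for c in self.df.columns if c.startswith(f"{task}:")]

    def families(self, task: str) -> list[str]:
        fams = []
        for c in self.feature_columns(task):
            fam = c.split(":")[1]
            if fam not in fams:
                fams.append(fam)
        return fams

    def family_columns(self, task: str, family: str) -> list[str]:
        return [c for c in self.df.columns if c.startswith(f"{task}:{family}:")]


def extract_cohort_features(cohort, tasks=("8MW", "9HPT"), lowpass_hz: float | None = None,
                            on_error: str = "flag") -> CohortTable:
    """Extract feature vectors for every visit-repeat of a synthetic cohort.

    Per-row failures are recorded (columns left NaN with a note in the
    ``extraction_error`` column) rather than aborting the whole table when
    ``on_error="flag"``; pass ``on_error="raise"`` to propagate.
    """
    labels = cohort.labels.set_index(["subject_id", "visit_id"])
    keys = sorted({(k[0], k[1], k[3]) for k in cohort.recordings})
    rows = []
    for sid, vid, rep in keys:
        row: dict = dict(subject_id=sid, visit_id=vid, repeat=rep)
        err = []
        if "8MW" in tasks:
            key = (sid, vid, "8MW", rep)
            if key in cohort.recordings:
                try:
                    kin = compute_kinematics(cohort.recordings[key], lowpass_hz=lowpass_hz)
                    seg = detect_strides(kin)
                    row.update(extract_gait_features(kin, seg).as_series().to_dict())
                except Exception as exc:  # noqa: BLE001
                    if on_error == "raise":
                        raise
                    err.append(f"8MW: {exc}")
        if "9HPT" in tasks:
            kin_hands = {}
            for hand in ("D", "ND"):
                key = (sid, vid, f"9HPT-{hand}", rep)
                if key in cohort.recordings:
                    kin_hands[hand] = compute_kinematics(cohort.recordings[key],
                                                         lowpass_hz=lowpass_hz)
            if kin_hands:
                try:
                    fv = extract_upperbody_features(kin_hands.get("D"), kin_hands.get("ND"))
                    row.update(fv.as_series().to_dict())
                except Exception as exc:  # noqa: BLE001
                    if on_error == "raise":
                        raise
                    err.append(f"9HPT: {exc}")
        try:
            lab = labels.loc[(sid, vid)]
            row.update({k: float(lab[k]) for k in ("SARA", "SCAFI", "FXN")})
            row["group"] = lab["group"]
            row["months"] = float(lab["months"])
        except KeyError:
            err.append("labels: missing")
            row["group"] = cohort.recordings[(sid, vid, "8MW", rep)].group \
                if (sid, vid, "8MW", rep) in cohort.recordings else ""
        row["extraction_error"] = "; ".join(err)
        rows.append(row)
    df = pd.DataFrame(rows)
    return CohortTable(df=df)


def build_feature_table(manifest: pd.DataFrame, labels: pd.DataFrame,
                        loader=None, tasks=("8MW", "9HPT"),
                        lowpass_hz: float | None = None) -> CohortTable:
    """File-based table construction from a recording manifest.

    ``manifest`` needs columns path, subject_id, visit_id, task, repeat,
    group, hand_dominance; ``labels`` joins on (subject_id, visit_id).
    Parsing and extraction failures are logged per row, not fatal.
    """
    from .skeleton_io import parse_bvh
    loader = loader or parse_bvh

    class _Shim:
        pass

    cohort = _Shim()
    cohort.recordings = {}
    for _, m in manifest.sort_values(["subject_id", "visit_id", "task", "repeat"]).iterrows():
        rec = loader(m["path"], subject_id=m["subject_id"], visit_id=m["visit_id"],
                     task=m["task"], group=m.get("group", "patient"),
                     hand_dominance=m.get("hand_dominance", "right"))
        cohort.recordings[(m["subject_id"], m["visit_id"], m["task"], int(m["repeat"]))] = rec
    cohort.labels = labels
    return extract_cohort_features(cohort, tasks=tasks, lowpass_hz=lowpass_hz)


# ---------------------------------------------------------------------------
# Validation screens
# ---------------------------------------------------------------------------

def test_retest_correlation(table: CohortTable, task: str | None = None) -> pd.Series:
    """Pearson r between repeat-1 and repeat-2 feature values per feature.

    Correlates across subject-visits that have both repeats; constant
    features (undefined r) are reported as NaN.
    """
    df = table.df
    cols = [c for c in df.columns if ":" in c and (task is None or c.startswith(task))]
    r1 = df[df["repeat"] == 1].set_index(["subject_id", "visit_id"])[cols]
    r2 = df[df["repeat"] == 2].set_index(["subject_id", "visit_id"])[cols]
    common = r1.index.intersection(r2.index)
    if len(common) < 3:
        raise ValueError("need at least 3 subject-visits with both repeats")
    out = {}
    for c in cols:
        a, b = r1.loc[common, c].to_numpy(), r2.loc[common, c].to_numpy()
        m = np.isfinite(a) & np.isfinite(b)
        if m.sum() < 3 or a[m].std() == 0 or b[m].std() == 0:
            out[c] = np.nan
        else:
            out[c] = float(np.corrcoef(a[m], b[m])[0, 1])
    return pd.Series(out, name="test_retest_r")


def group_difference_screen(table: CohortTable, feature: str):
    """Kruskal–Wallis patient-vs-control screen for one feature column."""
    df = table.df
    vals = {g: df.loc[(df["group"] == g) & np.isfinite(df[feature]), feature].to_numpy()
            for g in ("patient", "control")}
    for g, v in vals.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 rows")
    stat, p = sstats.kruskal(vals["patient"], vals["control"])
    return float(stat), float(p)


def paired_hand_test(values_d: np.ndarray, values_nd: np.ndarray):
    """Paired t test for dominant-vs-nondominant comparisons (e.g. F12, F16)."""
    stat, p = sstats.ttest_rel(values_d, values_nd)
    return float(stat), float(p)
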