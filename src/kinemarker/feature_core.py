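"""Signal and geometry primitives behind the kinematic feature families.

These operators are deliberately generic — voxel occupancy and its entropy,
autocorrelation curves and their principal components, delay-embedded
cross-correlation eigen spectra, PCA movement complexity, short-time RMS
power, logistic scale fits, convex-hull head-plane area and pairwise Pearson
correlations.  The task-level feature vectors in :mod:`kinemarker.task_features`
are thin assemblies of these primitives.

Conventions: distances in cm, angles in degrees, time in seconds; entropies in
nats; eigen spectra sorted descending and normalized to sum 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "VoxelOccupancy",
    "EigenSpectrum",
    "ComplexityResult",
    "LogisticFit",
    "voxel_occupancy",
    "workspace_volume",
    "workspace_entropy",
    "autocorrelation",
    "autocorr_cycle_pcs",
    "autocorr_fwhm",
    "delay_crosscorr_spectrum",
    "pca_complexity",
    "stft_rms_power",
    "cycle_energy",
    "fit_logistic_scale",
    "aic_model_select",
    "head_plane_area",
    "pairwise_pearson",
]


# ---------------------------------------------------------------------------
# Workspace occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelOccupancy:
    """Occupancy counts of 3D points on a regular voxel grid.

    ``counts`` maps an integer voxel index triple to the number of samples
    that fell into it; ``origin`` is the grid anchor (component-wise minimum
    snapped to the edge grid).
    """

    edge_cm: float
    origin: tuple[float, float, float]
    counts: dict[tuple[int, int, int], int]
    total: int

    def __post_init__(self):
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of counts")
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("counts must be strictly positive")

    @property
    def n_nonempty(self) -> int:
        return len(self.counts)


def voxel_occupancy(points: np.ndarray, edge_cm: float = 2.0) -> VoxelOccupancy:
    """Bin 3D points into a grid of ``edge_cm`` cubic voxels.

    The grid origin is the component-wise minimum of the points snapped to a
    multiple of the edge length, so the voxel structure is invariant under
    whole-grid translations of the data.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
        raise ValueError("points must be a nonempty N x 3 array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    if edge_cm <= 0:
        raise ValueError("edge_cm must be positive")
    origin = np.floor(pts.min(axis=0) / edge_cm) * edge_cm
    idx = np.floor((pts - origin) / edge_cm).astype(int)
    uniq, cnt = np.unique(idx, axis=0, return_counts=True)
    counts = {tuple(int(v) for v in u): int(c) for u, c in zip(uniq, cnt)}
    return VoxelOccupancy(edge_cm=float(edge_cm), origin=tuple(float(v) for v in origin),
                          counts=counts, total=int(pts.shape[0]))


def workspace_volume(occ: VoxelOccupancy) -> float:
    """Workspace volume in cm^3: nonempty voxel count times the voxel volume."""
    return occ.n_nonempty * occ.edge_cm ** 3


def workspace_entropy(occ: VoxelOccupancy) -> float:
    """Mean negative log occupancy probability over nonempty voxels (nats).

    With occupancy probabilities ``p_i = counts_i / total`` over the K
    nonempty voxels, H = (1/K) * sum_i(-ln p_i).  H = 0 when a single voxel is
    occupied and H = ln K when occupancy is uniform over K voxels.
    """
    c = np.fromiter(occ.counts.values(), dtype=float)
    p = c / occ.total
    return float(np.mean(-np.log(p)))


# ---------------------------------------------------------------------------
# Autocorrelation
# ---------------------------------------------------------------------------

def autocorrelation(signal: np.ndarray, max_lag_frames: int) -> np.ndarray:
    """Biased, mean-removed, variance-normalized autocorrelation at lags 0..max.

    The biased (1/N) estimator is used, so the curve decays for finite samples
    and equals 1 at lag 0 exactly.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size <= max_lag_frames:
        raise ValueError("signal must be longer than max_lag_frames")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("autocorrelation of a zero-variance signal is undefined")
    return _sm_acf(x, nlags=max_lag_frames, fft=True, adjusted=False)


def autocorr_cycle_pcs(curves: np.ndarray, mean_cycle_s: float, frame_rate: float,
                       n_bins: int = 50, span_cycles: float = 2.0):
    """Cycle-binned autocorrelation curves and their principal components.

    Each channel's autocorrelation curve is averaged into ``n_bins`` bins of
    width ``span_cycles/n_bins`` of a walk cycle (defaults: 50 bins of 4%,
    spanning 0–200% of the cycle).  PCA is then run over the channels x bins
    matrix (channels are observations, bins variables, column-mean-centred).

    Returns
    -------
    pc_curves : (n_bins, n_pcs) array of component curves (unit vectors),
        sign-fixed so each curve's value at bin 0 is >= 0.
    explained_variance : ratio per component.
    pc_values_at_cycle1 : values of PC curves 1 and 2 at the bin containing a
        lag of 100% of the cycle.
    degenerate : True when the channels have (numerically) no variance across
        observations, in which case the spectrum is defined as [1, 0, ...].
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    n_ch, n_lags = curves.shape
    bin_width_s = span_cycles * mean_cycle_s / n_bins
    lag_s = np.arange(n_lags) / frame_rate
    if lag_s[-1] + 1.0 / frame_rate < span_cycles * mean_cycle_s:
        raise ValueError(
            f"curves span {lag_s[-1]:.3f}s of lag; need {span_cycles * mean_cycle_s:.3f}s "
            f"({span_cycles} cycles)")
    bins = np.minimum((lag_s / bin_width_s).astype(int), n_bins - 1)
    keep = lag_s < span_cycles * mean_cycle_s
    binned = np.empty((n_ch, n_bins), dtype=float)
    for b in range(n_bins):
        m = keep & (bins == b)
        if not np.any(m):
            raise ValueError("autocorrelation sampling too coarse for the bin width")
        binned[:, b] = curves[:, m].mean(axis=1)

    centered = binned - binned.mean(axis=0, keepdims=True)
    # bin containing lag = 100% of the cycle
    cycle1_bin = min(int(round(1.0 * n_bins / span_cycles)), n_bins - 1)
    tot = float(np.sum(centered ** 2))
    if tot < 1e-12 * max(1.0, float(np.sum(binned ** 2))):
        # all channels identical: rank-0 covariance; report the common profile
        direction = binned[0] / (np.linalg.norm(binned[0]) or 1.0)
        if direction[0] < 0:
            direction = -direction
        evr = np.zeros(min(n_ch, n_bins))
        evr[0] = 1.0
        pc_curves = np.zeros((n_bins, len(evr)))
        pc_curves[:, 0] = direction
        vals = (float(pc_curves[cycle1_bin, 0]),
                float(pc_curves[cycle1_bin, 1]) if pc_curves.shape[1] > 1 else 0.0)
        return pc_curves, evr, vals, True

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    evr = s ** 2 / np.sum(s ** 2)
    pcs = vt  # rows are component curves over bins
    signs = np.where(pcs[:, 0] >= 0, 1.0, -1.0)
    pcs = pcs * signs[:, None]
    pc_curves = pcs.T
    v1 = float(pc_curves[cycle1_bin, 0])
    v2 = float(pc_curves[cycle1_bin, 1]) if pc_curves.shape[1] > 1 else 0.0
    return pc_curves, evr, (v1, v2), False


def autocorr_fwhm(curve: np.ndarray, frame_rate: float) -> tuple[float, bool]:
    """Full width at half maximum of an autocorrelation curve.

    The curve is symmetric about lag 0, so the width is twice the first lag at
    which it falls below 0.5 (linearly interpolated between samples).  If the
    curve never falls below 0.5 within its span, the width saturates at twice
    the maximum lag and the returned flag is True.
    """
    c = np.asarray(curve, dtype=float).ravel()
    below = np.nonzero(c < 0.5)[0]
    if below.size == 0:
        return 2.0 * (len(c) - 1) / frame_rate, True
    k = int(below[0])
    if k == 0:
        return 0.0, False
    # linear interpolation between samples k-1 and k
    frac = (c[k - 1] - 0.5) / (c[k - 1] - c[k])
    tau = (k - 1 + frac) / frame_rate
    return 2.0 * tau, False


# ---------------------------------------------------------------------------
# Delay-embedded cross-correlation spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EigenSpectrum:
    """Eigenvalues sorted descending and normalized to sum 1."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-9):
            raise ValueError("eigenvalues must be non-negative (tolerance -1e-9)")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("eigen spectrum must sum to 1")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("eigen spectrum must be non-increasing")

    @property
    def n(self) -> int:
        return len(self.values)

    def at_rank(self, rank: int) -> float:
        """1-based rank lookup (rank 1 = largest eigenvalue)."""
        if not 1 <= rank <= self.n:
            raise IndexError(f"rank {rank} outside 1..{self.n}")
        return float(self.values[rank - 1])


def delay_crosscorr_spectrum(channels: np.ndarray, lags: np.ndarray,
                             time_stride: int = 1) -> EigenSpectrum:
    """Eigen spectrum of the channel-delay cross-correlation matrix.

    Builds the correlation matrix of the stacked delay-embedded vector
    ``[x_c(t - l)]`` over all channels ``c`` and delays ``l`` (a C·L x C·L
    block matrix whose diagonal blocks hold within-channel autocorrelations
    and off-diagonal blocks cross-channel correlations), then returns its
    eigenvalues sorted descending, clipped at zero and normalized to sum 1.

    The eigenvalues are computed from the T x T Gram matrix of the
    standardized design matrix, which shares the nonzero spectrum of the
    C·L x C·L correlation matrix and is far cheaper when C·L is large;
    ``time_stride`` optionally subsamples the valid time axis.
    """
    X = np.atleast_2d(np.asarray(channels, dtype=float))
    C, T = X.shape
    if C < 2:
        raise ValueError("need at least 2 channels")
    sds = X.std(axis=1)
    dead = np.nonzero(sds == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance channel(s): {dead.tolist()}")
    lags = np.asarray(lags, dtype=int)
    max_lag = int(lags.max())
    if T <= max_lag + 1:
        raise ValueError("series must be longer than the maximum lag")
    t = np.arange(max_lag, T)[::time_stride]
    n_t = len(t)
    L = len(lags)
    D = np.empty((n_t, C * L), dtype=float)
    for li, lag in enumerate(lags):
        D[:, li * C:(li + 1) * C] = X[:, t - lag].T
    D -= D.mean(axis=0, keepdims=True)
    col_sd = D.std(axis=0)
    col_sd[col_sd == 0] = 1.0  # fully static delayed copy: contributes 0 variance
    D /= col_sd
    if n_t <= C * L:
        G = (D @ D.T) / n_t
        ev = np.linalg.eigvalsh(G)
        full = np.zeros(C * L)
        full[: n_t] = ev[::-1]
        ev = full
    else:
        R = (D.T @ D) / n_t
        ev = np.linalg.eigvalsh(R)[::-1]
    ev = np.clip(ev, 0.0, None)
    ev = np.sort(ev)[::-1]
    s = ev.sum()
    if s <= 0:
        raise ValueError("degenerate correlation matrix")
    return EigenSpectrum(values=ev / s)


# ---------------------------------------------------------------------------
# PCA movement complexity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityResult:
    """Movement complexity from the PCA residual-variance curve.

    ``complexity_pct`` is the area under the residual-variance curve
    r(k) = 1 − cumulative explained variance after k components, plotted over
    k/n, normalized by the area of the upper-left triangle (1/2) and expressed
    as a percentage: isotropic motion scores ~100%, one-dimensional motion
    near 0%.  Higher values mean more degrees of freedom are genuinely used —
    the direction in which ataxic movement differs from normal movement.
    """

    complexity_pct: float
    n_pcs_for: dict[float, int] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.complexity_pct <= 100.0 + 1e-9:
            raise ValueError("complexity_pct must be in [0, 100]")
        thresholds = sorted(self.n_pcs_for)
        ks = [self.n_pcs_for[t] for t in thresholds]
        if any(b < a for a, b in zip(ks, ks[1:])):
            raise ValueError("n_pcs_for must be monotone in the threshold")


def pca_complexity(channels: np.ndarray, thresholds=(0.8, 0.9)) -> ComplexityResult:
    """PCA on z-scored channels; complexity % and PCs-to-threshold counts."""
    X = np.atleast_2d(np.asarray(channels, dtype=float))
    n_ch, T = X.shape
    if n_ch < 2 or T < 2:
        raise ValueError("need at least 2 channels and 2 frames")
    sd = X.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise ValueError("rank-0 input: all channels constant")
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    cov = (Z @ Z.T) / T
    ev = np.clip(np.linalg.eigvalsh(cov)[::-1], 0.0, None)
    tot = ev.sum()
    if tot <= 0:
        raise ValueError("rank-0 input")
    cum = np.concatenate([[0.0], np.cumsum(ev) / tot])  # k = 0..n
    resid = 1.0 - cum
    x = np.arange(n_ch + 1) / n_ch
    area = float(np.trapezoid(resid, x))
    pct = 100.0 * area / 0.5
    n_pcs = {float(q): int(np.searchsorted(cum, q - 1e-12)) for q in thresholds}
    return ComplexityResult(complexity_pct=min(pct, 100.0), n_pcs_for=n_pcs)


# ---------------------------------------------------------------------------
# STFT RMS power
# ---------------------------------------------------------------------------

def stft_rms_power(signal: np.ndarray, frame_rate: float, window_s: float = 0.2,
                   overlap_s: float = 0.1, lowpass_hz: float | None = 10.0):
    """Short-time spectral RMS of a signal.

    The signal is optionally low-pass filtered (4th-order zero-phase
    Butterworth), split into Hann windows of ``window_s`` with ``overlap_s``
    overlap, and each window's spectral magnitudes are summarized by their
    RMS.  Returns ``(times_s, rms)`` with one value per window centre.
    """
    x = np.asarray(signal, dtype=float).ravel()
    nper = int(round(window_s * frame_rate))
    nover = int(round(overlap_s * frame_rate))
    if nper < 2 or nover >= nper:
        raise ValueError("window must exceed overlap and span at least 2 samples")
    if x.size < nper:
        raise ValueError("signal shorter than the STFT window")
    if lowpass_hz is not None:
        if lowpass_hz >= frame_rate / 2:
            raise ValueError("lowpass_hz must be below Nyquist")
        b, a = butter_lowpass(lowpass_hz, frame_rate)
        x = filtfilt_safe(b, a, x)
    f, t, Z = sps.stft(x, fs=frame_rate, window="hann", nperseg=nper,
                       noverlap=nover, boundary=None, padded=False)
    rms = np.sqrt(np.mean(np.abs(Z) ** 2, axis=0))
    return t, rms


def cycle_energy(times_s: np.ndarray, rms: np.ndarray, boundaries_s: np.ndarray) -> float:
    """Mean per-stride area under the RMS curve.

    ``boundaries_s`` are stride-start times; the trapezoidal area of the RMS
    series within each stride is averaged over strides.  Strides containing
    fewer than two RMS samples are skipped.
    """
    boundaries_s = np.asarray(boundaries_s, dtype=float)
    if len(boundaries_s) < 2:
        raise ValueError("need at least 2 stride boundaries")
    areas = []
    for a, b in zip(boundaries_s[:-1], boundaries_s[1:]):
        m = (times_s >= a) & (times_s < b)
        if m.sum() >= 2:
            areas.append(np.trapezoid(rms[m], times_s[m]))
    if not areas:
        raise ValueError("no stride contained enough RMS samples")
    return float(np.mean(areas))


def butter_lowpass(cutoff_hz: float, frame_rate: float, order: int = 4):
    return sps.butter(order, cutoff_hz / (frame_rate / 2))


def filtfilt_safe(b, a, x, axis=-1):
    """Zero-phase filtering that tolerates short signals (shrinks padlen)."""
    padlen = min(3 * (max(len(a), len(b)) - 1), x.shape[axis] - 1)
    return sps.filtfilt(b, a, x, axis=axis, padlen=padlen)


# ---------------------------------------------------------------------------
# Parametric fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic distribution fit (location mu, scale sigma)."""

    mu: float
    sigma: float
    aic: float
    family: str = "logistic"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not np.isfinite(self.aic):
            raise ValueError("aic must be finite")


_FAMILIES = {
    "normal": stats.norm,
    "logistic": stats.logistic,
    "uniform": stats.uniform,
    "laplace": stats.laplace,
}


def _dist_aic(dist, samples) -> tuple[tuple, float]:
    params = dist.fit(samples)
    ll = np.sum(dist.logpdf(samples, *params))
    return params, 2 * len(params) - 2 * ll


def fit_logistic_scale(samples: np.ndarray, min_samples: int = 50) -> LogisticFit:
    """ML fit of a logistic distribution; AIC = 2k − 2 ln L with k = 2."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    if np.ptp(x) == 0:
        raise ValueError("zero-spread samples")
    (mu, sigma), aic = _dist_aic(stats.logistic, x)
    return LogisticFit(mu=float(mu), sigma=float(sigma), aic=float(aic))


def aic_model_select(samples: np.ndarray, families=("normal", "logistic", "uniform")) -> str:
    """Name of the AIC-minimizing distribution family among the candidates."""
    x = np.asarray(samples, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise ValueError("zero-spread samples")
    best, best_aic = None, np.inf
    for name in families:
        try:
            dist = _FAMILIES[name]
        except KeyError:
            raise ValueError(f"unknown family {name!r}") from None
        _, aic = _dist_aic(dist, x)
        if aic < best_aic:
            best, best_aic = name, aic
    return best


# ---------------------------------------------------------------------------
# Head-plane area
# ---------------------------------------------------------------------------

def head_plane_area(head_positions_hipframe: np.ndarray,
                    forward_axis=(0.0, 0.0, 1.0)):
    """Area and spread of trunk-referenced head motion in its movement plane.

    Head positions (relative to the pelvis) are projected onto the plane
    orthogonal to the mean pelvis-to-head axis; the in-plane frontal axis is
    the projection of ``forward_axis`` (anterior–posterior) and the sideways
    axis completes the basis (medio-lateral).  Returns
    ``(hull_area_cm2, frontal_sd_cm, sideways_sd_cm, degenerate)``; collinear
    projections yield area 0 with the degeneracy flag set.
    """
    P = np.asarray(head_positions_hipframe, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 head positions (N x 3)")
    axis = P.mean(axis=0)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        axis = np.array([0.0, 1.0, 0.0])
    else:
        axis = axis / nrm
    fwd = np.asarray(forward_axis, dtype=float)
    fwd = fwd - (fwd @ axis) * axis
    if np.linalg.norm(fwd) < 1e-9:
        # forward parallel to the trunk axis: pick any orthogonal direction
        fwd = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    fwd = fwd / np.linalg.norm(fwd)
    side = np.cross(axis, fwd)
    uv = np.column_stack([P @ fwd, P @ side])
    uv_c = uv - uv.mean(axis=0)
    frontal_sd = float(uv_c[:, 0].std())
    sideways_sd = float(uv_c[:, 1].std())
    try:
        hull = ConvexHull(uv)
        area = float(hull.volume)  # 2-D hull: .volume is the area
        degenerate = False
    except QhullError:
        area, degenerate = 0.0, True
    return area, frontal_sd, sideways_sd, degenerate


def pairwise_pearson(signals: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Pearson r for every unordered pair of named equal-length series."""
    names = list(signals)
    arrs = [np.asarray(signals[n], dtype=float).ravel() for n in names]
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise ValueError("all series must have the same length")
    for n, a in zip(names, arrs):
        if a.std() == 0:
            raise ValueError(f"zero-variance series {n!r}")
    R = np.corrcoef(np.vstack(arrs))
    out = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out[(names[i], names[j])] = float(R[i, j])
    return out
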