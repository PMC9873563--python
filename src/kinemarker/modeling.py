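"""Gaussian-process prediction of clinical scores from kinematic features.

The estimator follows the study design end to end: a GP regression maps the
task feature vectors onto a clinical target (SARA, SCAFI or the FXN
normalized-Ct level), evaluated by *nested* leave-one-subject-out (LOSO)
cross-validation.  The outer loop holds out all rows (visits and repeats) of
one subject; the inner loop, run only on the remaining subjects, exhaustively
scores feature-family subsets by inner-LOSO RMSE and proposes the best subset
per outer fold.  The subset proposed most often across the outer folds is
selected (frequency measures robustness of the selection to training-set
changes), and the final metrics aggregate the outer-fold predictions made
with that subset.  Feature selection therefore never sees the held-out
subject.

The interface is organised statsmodels-style: :class:`ClinicalScoreGP` is the
model built from a cohort table, ``fit()`` returns a
:class:`ClinicalScoreGPResults` carrying out-of-fold predictions, R²/RMSE,
the selected subset, a ``summary()`` table, the cohort-size learning-curve
analysis and a prediction plot.

The GP itself uses an isotropic RBF (or Matérn-5/2) kernel on standardized
features plus observation noise; the posterior is computed in closed form
(Cholesky), and inner-LOSO predictions use the exact block leave-one-out
identity on the inverse kernel matrix, which makes the exhaustive subset
search tractable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .task_features import CohortTable

__all__ = [
    "GPModelSpec",
    "PredictionResult",
    "LearningCurve",
    "ClinicalScoreGP",
    "ClinicalScoreGPResults",
    "gp_fit_predict",
    "nested_loso_evaluate",
    "learning_curve",
    "r2_rmse",
    "scafi_composite",
    "gaa_repeats_from_pcr",
    "permute_labels_across_subjects",
]


@dataclass(frozen=True)
class GPModelSpec:
    """GP kernel family and hyperparameter grid.

    Length scales are in units of sqrt(d) on standardized d-dimensional
    features, so a multiplier of 1 matches the typical inter-point distance
    regardless of how many feature families are active.  Noise variances are
    relative to unit target variance.  The grid point used for the final
    per-fold predictions is chosen by inner-LOSO error.
    """

    kernel: str = "rbf"  # "rbf" | "matern52"
    length_scale_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    noise_grid: tuple[float, ...] = (0.005, 0.05, 0.2, 0.5)
    inner_length_scale: float = 1.0
    inner_noise: float = 0.2
    jitter: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if not self.length_scale_grid or not self.noise_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if min(self.noise_grid) <= 0 or self.inner_noise <= 0:
            raise ValueError("noise variance must be positive")
        if self.kernel not in ("rbf", "matern52"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def _kernel_from_sqdist(D: np.ndarray, ell: float, kernel: str) -> np.ndarray:
    if kernel == "rbf":
        return np.exp(-D / (2.0 * ell * ell))
    r = np.sqrt(np.maximum(D, 0.0)) * (math.sqrt(5.0) / ell)
    return (1.0 + r + r * r / 3.0) * np.exp(-r)


def gp_fit_predict(X_train, y_train, X_test, spec: GPModelSpec | None = None,
                   length_scale: float | np.ndarray = 1.0, noise: float = 0.2):
    """Closed-form GP posterior mean and sd for test rows.

    Features are standardized with training statistics only and the target is
    centred/scaled on the training rows; ``length_scale`` is in units of
    sqrt(d) (a vector gives per-dimension ARD-style scales).  Returns
    ``(mean, sd)`` on the original target scale; the sd is the latent
    posterior sd (excluding observation noise).
    """
    spec = spec or GPModelSpec()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y = np.asarray(y_train, dtype=float).ravel()
    if len(y) < 3:
        raise ValueError("need at least 3 training rows")
    mu_x = X_train.mean(axis=0)
    sd_x = X_train.std(axis=0)
    sd_x[sd_x == 0] = 1.0
    Ztr = (X_train - mu_x) / sd_x
    Zte = (X_test - mu_x) / sd_x
    ls = np.asarray(length_scale, dtype=float)
    if ls.ndim > 0 and ls.size == Ztr.shape[1]:
        Ztr = Ztr / ls
        Zte = Zte / ls
        ell = math.sqrt(Ztr.shape[1])
    else:
        ell = float(ls) * math.sqrt(Ztr.shape[1])
    mu_y, sd_y = y.mean(), y.std()
    if sd_y == 0:
        sd_y = 1.0
    yz = (y - mu_y) / sd_y
    K = _kernel_from_sqdist(cdist(Ztr, Ztr, "sqeuclidean"), ell, spec.kernel)
    K[np.diag_indices_from(K)] += noise + spec.jitter
    try:
        cf = cho_factor(K, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular kernel matrix after jitter: {exc}") from exc
    alpha = cho_solve(cf, yz)
    Ks = _kernel_from_sqdist(cdist(Zte, Ztr, "sqeuclidean"), ell, spec.kernel)
    mean = Ks @ alpha
    v = cho_solve(cf, Ks.T)
    var = np.clip(1.0 - np.sum(Ks * v.T, axis=1), 0.0, None)
    return mu_y + sd_y * mean, sd_y * np.sqrt(var)


def _block_loo_predictions(K: np.ndarray, y: np.ndarray, blocks: list[np.ndarray],
                           noise: float, jitter: float) -> np.ndarray:
    """Exact leave-one-block-out GP posterior means from one factorization.

    For a fixed kernel, the LOSO residual of block B satisfies
    ``resid_B = (K^-1)_BB^-1 (K^-1 y)_B``; one Cholesky serves every fold.
    """
    Kn = K.copy()
    Kn[np.diag_indices_from(Kn)] += noise + jitter
    cf = cho_factor(Kn, lower=True)
    Kinv = cho_solve(cf, np.eye(Kn.shape[0]))
    Ky = Kinv @ y
    pred = np.empty_like(y)
    for b in blocks:
        sub = Kinv[np.ix_(b, b)]
        resid = np.linalg.solve(sub, Ky[b])
        pred[b] = y[b] - resid
    return pred


def r2_rmse(truth, predicted) -> tuple[float, float]:
    """Aggregate coefficient of determination and root-mean-square error.

    R² = 1 − SSE/SST over the pooled predictions (can be negative); when the
    truth has zero variance R² is undefined and returned as NaN.
    """
    t = np.asarray(truth, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if t.size == 0 or t.size != p.size:
        raise ValueError("truth and predictions must be equal-length and nonempty")
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0:
        return float("nan"), rmse
    sse = float(np.sum((t - p) ** 2))
    return 1.0 - sse / sst, rmse


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Aggregated out-of-fold predictions and the selected feature subset."""

    predictions: pd.DataFrame  # subject_id, visit_id, repeat, y_true, y_pred, y_sd
    r2: float
    rmse: float
    selected_subset: tuple[str, ...]
    subset_frequency: int
    per_fold_subsets: dict[str, tuple[str, ...]]

    def __post_init__(self):
        if self.rmse < 0 or (np.isfinite(self.r2) and self.r2 > 1 + 1e-12):
            raise ValueError("invalid metrics")


@dataclass
class LearningCurve:
    """Mean/sd of aggregate LOSO RMSE versus cohort size k (nCk sampling)."""

    k_values: tuple[int, ...]
    mean_rmse: np.ndarray
    sd_rmse: np.ndarray
    n_combinations: tuple[int, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "mean_rmse": self.mean_rmse,
                             "sd_rmse": self.sd_rmse,
                             "n_combinations": self.n_combinations})


class ClinicalScoreGP:
    """GP clinical-score model over a cohort feature table.

    Parameters
    ----------
    table : CohortTable or DataFrame
        Subject-visit-repeat rows with feature and label columns.
    target : {"SARA", "SCAFI", "FXN"}
        Clinical target column.
    feature_set : {"8MW", "9HPT"}
        Which task's feature families to search over.
    mode : {"cross_sectional", "longitudinal"}
        Cross-sectional pairs each visit's features with the same visit's
        label.  Longitudinal pairs *baseline* features with the label at
        ``horizon_months`` later (patients only).
    max_subset_size : int
        Exhaustive search considers every family subset up to this size.
    include_controls : bool, optional
        Defaults: controls included for cross-sectional score prediction,
        excluded in longitudinal mode; rows without a finite target are
        always dropped (e.g. controls have no FXN sample).
    """

    def __init__(self, table, target: str = "SARA", feature_set: str = "8MW",
                 mode: str = "cross_sectional", horizon_months: float = 9.0,
                 spec: GPModelSpec | None = None, max_subset_size: int = 4,
                 include_controls: bool | None = None):
        if isinstance(table, pd.DataFrame):
            table = CohortTable(df=table)
        if target not in ("SARA", "SCAFI", "FXN"):
            raise ValueError(f"unknown target {target!r}")
        if feature_set not in ("8MW", "9HPT"):
            raise ValueError(f"unknown feature_set {feature_set!r}")
        if mode not in ("cross_sectional", "longitudinal"):
            raise ValueError(f"unknown mode {mode!r}")
        self.table = table
        self.target = target
        self.feature_set = feature_set
        self.mode = mode
        self.horizon_months = horizon_months
        self.spec = spec or GPModelSpec()
        self.max_subset_size = max_subset_size
        if include_controls is None:
            include_controls = mode == "cross_sectional"
        self.include_controls = include_controls
        self.families = table.families(feature_set)
        if not self.families:
            raise ValueError(f"table has no {feature_set} feature columns")
        self.frame = self._build_frame()

    # -- data assembly ----------------------------------------------------

    def _build_frame(self) -> pd.DataFrame:
        df = self.table.df
        cols = self.table.feature_columns(self.feature_set)
        if self.mode == "cross_sectional":
            frame = df[CohortTable.KEY + ["group", self.target] + cols].copy()
            frame = frame.rename(columns={self.target: "y"})
        else:
            pat = df[df["group"] == "patient"]
            base = pat[np.isclose(pat["months"], pat.groupby("subject_id")["months"]
                                  .transform("min"))]
            later = pat[np.isclose(pat["months"], self.horizon_months)]
            lab = later.groupby("subject_id")[self.target].mean()
            frame = base[CohortTable.KEY + ["group"] + cols].copy()
            frame["y"] = frame["subject_id"].map(lab)
            dropped = sorted(frame.loc[frame["y"].isna(), "subject_id"].unique())
            if dropped:
                warnings.warn(f"longitudinal horizon {self.horizon_months} months: "
                              f"dropping subjects without a matching visit: {dropped}")
        if not self.include_controls:
            frame = frame[frame["group"] == "patient"]
        feat_ok = np.isfinite(frame[cols].to_numpy(dtype=float)).all(axis=1)
        frame = frame[feat_ok & np.isfinite(frame["y"])]
        if frame.empty:
            raise ValueError(f"target {self.target!r} has no usable rows")
        subjects = frame["subject_id"].nunique()
        if subjects < 4:
            raise ValueError(f"need >= 4 subjects, have {subjects}")
        return frame.reset_index(drop=True)

    # -- internals ---------------------------------------------------------

    def _family_sqdists(self, Z: np.ndarray, fam_slices: dict[str, np.ndarray]):
        return {f: cdist(Z[:, idx], Z[:, idx], "sqeuclidean")
                for f, idx in fam_slices.items()}

    def _subsets(self) -> list[tuple[str, ...]]:
        subs = []
        for size in range(1, self.max_subset_size + 1):
            subs.extend(itertools.combinations(self.families, size))
        return subs

    @staticmethod
    def _standardize(X: np.ndarray, train_mask: np.ndarray) -> np.ndarray:
        mu = X[train_mask].mean(axis=0)
        sd = X[train_mask].std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    def _inner_select(self, D_all: dict[str, np.ndarray], fam_dims: dict[str, int],
                      y: np.ndarray, train_idx: np.ndarray,
                      subject_of: np.ndarray) -> tuple[tuple[str, ...], dict]:
        """Best subset on the training rows by inner block-LOSO RMSE."""
        spec = self.spec
        ytr = y[train_idx]
        mu, sd = ytr.mean(), ytr.std() or 1.0
        yz = (ytr - mu) / sd
        subs_tr = subject_of[train_idx]
        blocks = [np.nonzero(subs_tr == s)[0] for s in pd.unique(subs_tr)]
        scores = {}
        for subset in self._subsets():
            Dsum = sum(D_all[f][np.ix_(train_idx, train_idx)] for f in subset)
            d = sum(fam_dims[f] for f in subset)
            ell = spec.inner_length_scale * math.sqrt(d)
            K = _kernel_from_sqdist(Dsum, ell, spec.kernel)
            pred = _block_loo_predictions(K, yz, blocks, spec.inner_noise, spec.jitter)
            scores[subset] = float(np.sqrt(np.mean((pred - yz) ** 2)))
        best = min(scores, key=lambda s: (scores[s], s))
        return best, scores

    def _grid_search(self, Dsum_tr: np.ndarray, d: int, yz: np.ndarray,
                     blocks) -> tuple[float, float]:
        spec = self.spec
        best, best_rmse = (spec.inner_length_scale, spec.inner_noise), np.inf
        for lm in spec.length_scale_grid:
            K = _kernel_from_sqdist(Dsum_tr, lm * math.sqrt(d), spec.kernel)
            for nv in spec.noise_grid:
                pred = _block_loo_predictions(K, yz, blocks, nv, spec.jitter)
                rmse = float(np.sqrt(np.mean((pred - yz) ** 2)))
                if rmse < best_rmse - 1e-12:
                    best, best_rmse = (lm, nv), rmse
        return best

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "ClinicalScoreGPResults":
        frame = self.frame
        cols = self.table.feature_columns(self.feature_set)
        fam_slices = {}
        for f in self.families:
            fam_slices[f] = np.asarray(
                [i for i, c in enumerate(cols) if c.split(":")[1] == f], dtype=int)
        fam_dims = {f: len(ix) for f, ix in fam_slices.items()}
        X = frame[cols].to_numpy(dtype=float)
        y = frame["y"].to_numpy(dtype=float)
        subjects = frame["subject_id"].to_numpy()
        subj_list = list(pd.unique(subjects))
        subject_of = np.asarray([subj_list.index(s) for s in subjects])

        fold_subsets: dict[str, tuple[str, ...]] = {}
        fold_scores: dict[str, dict] = {}
        fold_cache: dict[str, tuple] = {}
        for si, subj in enumerate(subj_list):
            test_mask = subject_of == si
            train_idx = np.nonzero(~test_mask)[0]
            Z = self._standardize(X, ~test_mask)
            D_all = self._family_sqdists(Z, fam_slices)
            best, scores = self._inner_select(D_all, fam_dims, y, train_idx, subject_of)
            fold_subsets[subj] = best
            fold_scores[subj] = scores
            fold_cache[subj] = (Z, D_all, train_idx, np.nonzero(test_mask)[0])

        counts: dict[tuple[str, ...], int] = {}
        for s in fold_subsets.values():
            counts[s] = counts.get(s, 0) + 1
        top = max(counts.values())
        candidates = [s for s, c in counts.items() if c == top]
        if len(candidates) > 1:
            mean_rmse = {s: float(np.mean([fold_scores[subj][s] for subj in subj_list]))
                         for s in candidates}
            candidates.sort(key=lambda s: (mean_rmse[s], s))
        selected = candidates[0]
        sel_dim = sum(fam_dims[f] for f in selected)

        preds = np.empty(len(frame))
        sds = np.empty(len(frame))
        for subj in subj_list:
            Z, D_all, train_idx, test_idx = fold_cache[subj]
            Dsum = sum(D_all[f] for f in selected)
            ytr = y[train_idx]
            mu, sd = ytr.mean(), ytr.std() or 1.0
            yz = (ytr - mu) / sd
            subs_tr = subject_of[train_idx]
            blocks = [np.nonzero(subs_tr == s)[0] for s in pd.unique(subs_tr)]
            lm, nv = self._grid_search(Dsum[np.ix_(train_idx, train_idx)], sel_dim,
                                       yz, blocks)
            ell = lm * math.sqrt(sel_dim)
            Ktr = _kernel_from_sqdist(Dsum[np.ix_(train_idx, train_idx)], ell,
                                      self.spec.kernel)
            Ktr[np.diag_indices_from(Ktr)] += nv + self.spec.jitter
            cf = cho_factor(Ktr, lower=True)
            alpha = cho_solve(cf, yz)
            Kst = _kernel_from_sqdist(Dsum[np.ix_(test_idx, train_idx)], ell,
                                      self.spec.kernel)
            preds[test_idx] = mu + sd * (Kst @ alpha)
            v = cho_solve(cf, Kst.T)
            var = np.clip(1.0 - np.sum(Kst * v.T, axis=1), 0.0, None)
            sds[test_idx] = sd * np.sqrt(var)

        r2, rmse = r2_rmse(y, preds)
        pred_df = frame[CohortTable.KEY + ["group"]].copy()
        pred_df["y_true"] = y
        pred_df["y_pred"] = preds
        pred_df["y_sd"] = sds
        result = PredictionResult(predictions=pred_df, r2=r2, rmse=rmse,
                                  selected_subset=selected,
                                  subset_frequency=counts[selected],
                                  per_fold_subsets=dict(fold_subsets))
        return ClinicalScoreGPResults(model=self, result=result)


class ClinicalScoreGPResults:
    """Fitted nested-LOSO results: predictions, metrics, subset, diagnostics."""

    def __init__(self, model: ClinicalScoreGP, result: PredictionResult):
        self.model = model
        self._result = result

    @property
    def predictions(self) -> pd.DataFrame:
        return self._result.predictions

    @property
    def r2(self) -> float:
        return self._result.r2

    @property
    def rmse(self) -> float:
        return self._result.rmse

    @property
    def selected_subset(self) -> tuple[str, ...]:
        return self._result.selected_subset

    @property
    def subset_frequency(self) -> int:
        return self._result.subset_frequency

    @property
    def per_fold_subsets(self) -> dict[str, tuple[str, ...]]:
        return self._result.per_fold_subsets

    def summary(self) -> str:
        m = self.model
        n_subj = m.frame["subject_id"].nunique()
        lines = [
            "Clinical-score GP regression (nested leave-one-subject-out)",
            "=" * 62,
            f"Target:            {m.target:<12}  Mode:   {m.mode}",
            f"Feature set:       {m.feature_set:<12}  Kernel: {m.spec.kernel}",
            f"Subjects:          {n_subj:<12}  Rows:   {len(m.frame)}",
            f"Families searched: {len(m.families)} (subsets up to size {m.max_subset_size})",
            "-" * 62,
            f"Selected subset:   {' + '.join(self.selected_subset)}",
            f"Subset frequency:  {self.subset_frequency}/{n_subj} outer folds",
            f"Aggregate R2:      {self.r2:8.3f}",
            f"Aggregate RMSE:    {self.rmse:8.3f}",
            "=" * 62,
        ]
        return "\n".join(lines)

    def learning_curve(self, k_values, n_combinations_max: int = 1000,
                       seed: int | None = None) -> LearningCurve:
        return learning_curve(self.model.table, self.model.target, k_values,
                              spec=self.model.spec, seed=self.model.spec.seed
                              if seed is None else seed,
                              feature_set=self.model.feature_set, mode=self.model.mode,
                              horizon_months=self.model.horizon_months,
                              subset=self.selected_subset,
                              include_controls=self.model.include_controls,
                              n_combinations_max=n_combinations_max)

    def plot_predictions(self, ax=None):
        """Scatter of actual vs predicted scores, one point per row."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        df = self.predictions
        for grp, marker in (("patient", "o"), ("control", "s")):
            sub = df[df["group"] == grp]
            if len(sub):
                ax.errorbar(sub["y_true"], sub["y_pred"], yerr=sub["y_sd"], fmt=marker,
                            alpha=0.7, label=grp, capsize=2)
        lo = min(df["y_true"].min(), df["y_pred"].min())
        hi = max(df["y_true"].max(), df["y_pred"].max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
        ax.set_xlabel(f"actual {self.model.target}")
        ax.set_ylabel(f"predicted {self.model.target}")
        ax.legend()
        ax.set_title(f"R2={self.r2:.2f}, RMSE={self.rmse:.2f}")
        return ax


def nested_loso_evaluate(table, target: str, feature_set: str = "8MW",
                         mode: str = "cross_sectional", horizon_months: float = 9.0,
                         spec: GPModelSpec | None = None,
                         max_subset_size: int = 4,
                         include_controls: bool | None = None) -> PredictionResult:
    """Functional wrapper: build the model, fit, return the PredictionResult."""
    res = ClinicalScoreGP(table, target=target, feature_set=feature_set, mode=mode,
                          horizon_months=horizon_months, spec=spec,
                          max_subset_size=max_subset_size,
                          include_controls=include_controls).fit()
    return res._result


# ---------------------------------------------------------------------------
# Learning curve
# ---------------------------------------------------------------------------

def learning_curve(table, target: str, k_values, spec: GPModelSpec | None = None,
                   seed: int = 0, feature_set: str = "8MW",
                   mode: str = "cross_sectional", horizon_months: float = 9.0,
                   subset: tuple[str, ...] | None = None,
                   include_controls: bool | None = None,
                   n_combinations_max: int = 1000) -> LearningCurve:
    """Aggregate LOSO RMSE as a function of the number of participants k.

    For each k, up to ``n_combinations_max`` distinct k-subsets of the
    participants are drawn (all of them when C(n, k) is small enough); within
    each combination a LOSO evaluation is run with the pre-selected feature
    subset and the default kernel hyperparameters, and the mean and sd of the
    aggregate RMSE across combinations are reported.
    """
    spec = spec or GPModelSpec()
    model = ClinicalScoreGP(table, target=target, feature_set=feature_set, mode=mode,
                            horizon_months=horizon_months, spec=spec,
                            include_controls=include_controls)
    if subset is None:
        subset = tuple(model.families)
    frame = model.frame
    cols = model.table.feature_columns(feature_set)
    keep_cols = [i for i, c in enumerate(cols) if c.split(":")[1] in subset]
    d = len(keep_cols)
    X = frame[cols].to_numpy(dtype=float)[:, keep_cols]
    y = frame["y"].to_numpy(dtype=float)
    subjects = frame["subject_id"].to_numpy()
    subj_list = list(pd.unique(subjects))
    n = len(subj_list)
    rng = np.random.default_rng(seed)

    means, sds, ncombs = [], [], []
    for k in k_values:
        if k < 3 or k > n:
            raise ValueError(f"k={k} outside [3, {n}]")
        total = math.comb(n, k)
        if total <= n_combinations_max:
            combos = list(itertools.combinations(range(n), k))
        else:
            seen = set()
            while len(seen) < n_combinations_max:
                seen.add(tuple(sorted(rng.choice(n, size=k, replace=False))))
            combos = sorted(seen)
        rmses = []
        for combo in combos:
            mask = np.isin(subjects, [subj_list[i] for i in combo])
            Xc, yc, sc = X[mask], y[mask], subjects[mask]
            mu = Xc.mean(axis=0)
            sd = Xc.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (Xc - mu) / sd
            ell = spec.inner_length_scale * math.sqrt(d)
            K = _kernel_from_sqdist(cdist(Z, Z, "sqeuclidean"), ell, spec.kernel)
            muy, sdy = yc.mean(), yc.std() or 1.0
            yz = (yc - muy) / sdy
            blocks = [np.nonzero(sc == s)[0] for s in pd.unique(sc)]
            pred = _block_loo_predictions(K, yz, blocks, spec.inner_noise, spec.jitter)
            rmses.append(sdy * float(np.sqrt(np.mean((pred - yz) ** 2))))
        rmses = np.asarray(rmses)
        means.append(rmses.mean())
        sds.append(rmses.std())
        ncombs.append(len(combos))
    return LearningCurve(k_values=tuple(int(k) for k in k_values),
                         mean_rmse=np.asarray(means), sd_rmse=np.asarray(sds),
                         n_combinations=tuple(ncombs))


# ---------------------------------------------------------------------------
# Clinical utilities
# ---------------------------------------------------------------------------

def scafi_composite(t_8mw_s: float, t_9hpt_d_s: float, t_9hpt_nd_s: float,
                    pata_rate: float, baseline_stats: dict) -> float:
    """SCAFI-style composite: mean of z-scored subtest performances.

    Components are oriented so that higher = better performance: walk and peg
    times enter as 1/time, the PATA repetition count per 10 s as a rate.  Each
    component is expressed as standard deviations from the baseline-cohort
    mean using ``baseline_stats`` = {"8MW": (mean, sd), "9HPT": (mean, sd),
    "PATA": (mean, sd)} on those transformed scales, and the three z-scores
    are averaged.
    """
    if min(t_8mw_s, t_9hpt_d_s, t_9hpt_nd_s) <= 0 or pata_rate < 0:
        raise ValueError("times must be positive and the PATA rate non-negative")
    comp = {
        "8MW": 1.0 / t_8mw_s,
        "9HPT": 0.5 * (1.0 / t_9hpt_d_s + 1.0 / t_9hpt_nd_s),
        "PATA": pata_rate,
    }
    zs = []
    for name, value in comp.items():
        mean, sd = baseline_stats[name]
        if sd <= 0:
            raise ValueError(f"baseline sd for {name} must be positive")
        zs.append((value - mean) / sd)
    return float(np.mean(zs))


def gaa_repeats_from_pcr(pcr_product_bp: float) -> int:
    """GAA repeat count from a long-range PCR product size: (S_PCR − 282)/3.

    The amplicon carries 157 + 125 = 282 bp of flanking sequence around the
    triplet tract.  Product sizes under 282 bp are impossible and raise; a
    size not on the 3 bp grid is rounded to the nearest repeat with a warning.
    """
    if pcr_product_bp < 282:
        raise ValueError(f"PCR product of {pcr_product_bp} bp is shorter than the "
                         "282 bp flanking sequence")
    raw = (pcr_product_bp - 282) / 3.0
    n = round(raw)
    if abs(raw - n) > 1e-9:
        warnings.warn(f"product size {pcr_product_bp} bp is not a whole number of "
                      f"triplets; rounding {raw:.2f} to {n}")
    return int(n)


def permute_labels_across_subjects(table: CohortTable, target: str,
                                   seed: int = 0) -> CohortTable:
    """Null-model table: permute label trajectories across all subjects.

    Each subject's whole label trajectory is swapped with another (randomly
    chosen) subject's, aligned by visit order, destroying the feature-label
    association — including the patient/control alignment — while preserving
    the label marginal and the repeat structure.  A subject whose donor has
    fewer visits recycles the donor's last available visit.
    """
    df = table.df.copy()
    rng = np.random.default_rng(seed)
    subj = list(pd.unique(df["subject_id"]))
    mapping = dict(zip(subj, rng.permutation(subj)))
    lab = (df.drop_duplicates(["subject_id", "visit_id"])
           .set_index(["subject_id", "visit_id"])[CohortTable.LABELS])
    for s in subj:
        src_rows = lab.loc[mapping[s]]
        for vi, vid in enumerate(df.loc[df["subject_id"] == s, "visit_id"].unique()):
            vals = src_rows.iloc[min(vi, len(src_rows) - 1)]
            sel = (df["subject_id"] == s) & (df["visit_id"] == vid)
            for c in CohortTable.LABELS:
                df.loc[sel, c] = vals[c]
    return CohortTable(df=df)
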