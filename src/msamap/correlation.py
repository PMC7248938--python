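"""Shifted correlation between sensor features and the stimulus event train.

The method's core statistic: for each sensor locus, stack the time-frequency
features of its co-localized channels into a design matrix x(t) and compute
the multiple Pearson correlation (MPC) between x(t) and the binary event
train y(t - tau) over a grid of shifts tau. To avoid the overfitting that
comes with tens of correlated spectral predictors, the MPC is evaluated on
out-of-fold predictions from k-fold cross-validated ridge regression: R(tau)
is the Pearson correlation between the concatenated held-out predictions and
the shifted event train. The shift at which R peaks estimates the latency of
the task-related modulation relative to the stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import DegenerateInputError, TFFeatures

__all__ = [
    "EventTrain",
    "DesignMatrix",
    "RidgeModel",
    "FoldPlan",
    "MPCCurve",
    "MPCMap",
    "frame_event_train",
    "shifted_pc",
    "build_design_matrix",
    "ridge_fit",
    "cv_predict",
    "cv_mpc",
    "msa_map",
    "make_fold_plan",
    "default_shift_grid",
]


@dataclass(frozen=True)
class EventTrain:
    """Stimulus onsets and their frame-aligned binary indicator y(t)."""

    onset_times: np.ndarray   # s, onsets retained in the frame range
    y: np.ndarray             # (n_frames,) 0/1
    frame_times: np.ndarray   # s, copied from the features
    step: float               # s, frame step
    n_dropped: int = 0        # onsets outside the frame range
    n_merged: int = 0         # onsets collapsed onto an occupied frame

    @property
    def n_frames(self) -> int:
        return self.y.size

    @property
    def y_mean(self) -> float:
        return float(self.y.mean())

    @property
    def y_sd(self) -> float:
        return float(self.y.std())


@dataclass(frozen=True)
class DesignMatrix:
    """Per-locus predictor matrix, columns ordered channel-major then band."""

    X: np.ndarray                       # (frames, p)
    column_map: tuple[tuple[int, int], ...]  # column -> (channel, band)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class RidgeModel:
    """Fitted L2-penalized linear model y^ = b.x + intercept."""

    b: np.ndarray
    intercept: float
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.b + self.intercept


@dataclass(frozen=True)
class FoldPlan:
    """Contiguous, non-overlapping fold blocks covering all frames."""

    n_folds: int
    assignment: np.ndarray  # (n_frames,) fold id per frame


@dataclass(frozen=True)
class MPCCurve:
    """Correlation values over a shift grid for one locus."""

    shifts: np.ndarray
    values: np.ndarray
    n_folds: int | None = None
    lam: float | None = None
    degenerate: bool = False

    @property
    def peak_shift(self) -> float:
        return float(self.shifts[int(np.nanargmax(self.values))])

    @property
    def peak_value(self) -> float:
        return float(np.nanmax(self.values))


@dataclass(frozen=True)
class MPCMap:
    """Per-locus MPC curves stacked as a loci x shifts matrix."""

    shifts: np.ndarray
    values: np.ndarray              # (L, S); NaN rows for degenerate loci
    degenerate: np.ndarray          # (L,) bool
    n_folds: int
    lam: float

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    def curve(self, locus: int) -> MPCCurve:
        return MPCCurve(
            shifts=self.shifts, values=self.values[locus],
            n_folds=self.n_folds, lam=self.lam,
            degenerate=bool(self.degenerate[locus]),
        )

    def peak(self) -> tuple[int, float, float]:
        """(locus, shift, R) of the global maximum; lowest index wins ties."""
        flat = int(np.nanargmax(self.values))
        locus, s = np.unravel_index(flat, self.values.shape)
        return int(locus), float(self.shifts[s]), float(self.values[locus, s])


def frame_event_train(onset_times, features: TFFeatures) -> EventTrain:
    """Binary event train y on the feature frame grid.

    Each onset lights the nearest frame (ties go to the earlier frame).
    Onsets farther than half a step outside the frame range are dropped and
    counted; two onsets landing on one frame are merged with a warning.
    """
    onset_times = np.atleast_1d(np.asarray(onset_times, dtype=float))
    ft = features.frame_times
    step = features.step
    in_range = (onset_times >= ft[0] - step / 2) & (onset_times <= ft[-1] + step / 2)
    n_dropped = int((~in_range).sum())
    kept = onset_times[in_range]
    if kept.size == 0:
        raise ValueError("no onset falls within the feature frame range")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} onset(s) outside the frame range",
                      stacklevel=2)

    right = np.searchsorted(ft, kept)
    idx = np.empty(kept.size, dtype=np.int64)
    for j, (onset, r) in enumerate(zip(kept, right)):
        if r == 0:
            idx[j] = 0
        elif r == ft.size:
            idx[j] = ft.size - 1
        else:
            # tie (exact midpoint) resolves to the earlier frame
            idx[j] = r - 1 if onset - ft[r - 1] <= ft[r] - onset else r

    y = np.zeros(ft.size, dtype=np.int8)
    n_merged = int(kept.size - np.unique(idx).size)
    if n_merged:
        warnings.warn(f"merged {n_merged} onset(s) sharing a frame", stacklevel=2)
    y[idx] = 1
    return EventTrain(onset_times=kept, y=y, frame_times=ft.copy(), step=step,
                      n_dropped=n_dropped, n_merged=n_merged)


def _lag_of(shift: float, step: float) -> int:
    lag = shift / step
    k = int(round(lag))
    if abs(lag - k) > 1e-6:
        raise ValueError(
            f"shift {shift:g} s is not an integer multiple of the frame "
            f"step {step:g} s"
        )
    return k


def _overlap(n: int, lag: int) -> tuple[slice, slice]:
    """Slices (x_rows, y_rows) pairing x[i] with y[i - lag]."""
    if lag >= 0:
        return slice(lag, n), slice(0, n - lag)
    return slice(0, n + lag), slice(-lag, n)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateInputError("zero-variance series in correlation")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def shifted_pc(xf: np.ndarray, ev: EventTrain, shifts) -> MPCCurve:
    """Shifted simple Pearson correlation R_f(tau) of one feature column.

    For each shift tau (an integer number of frames), correlates x_f(t) with
    y(t - tau) over the overlapping frame range.
    """
    xf = np.asarray(xf, dtype=float)
    if xf.std() == 0:
        raise DegenerateInputError("feature column has zero variance")
    shifts = np.atleast_1d(np.asarray(shifts, dtype=float))
    n = ev.n_frames
    values = np.empty(shifts.size)
    for i, tau in enumerate(shifts):
        sx, sy = _overlap(n, _lag_of(tau, ev.step))
        values[i] = _pearson(xf[sx], ev.y[sy].astype(float))
    return MPCCurve(shifts=shifts, values=values)


def build_design_matrix(features: TFFeatures, locus: int,
                        band_subset=None) -> DesignMatrix:
    """Stack a locus's channels x bands features into one predictor matrix.

    Columns are channel-major then band, matching the stacking
    x(t) = (x1(t), x2(t)) of per-channel spectral vectors.
    """
    if features.channel_locus is None:
        raise ValueError("features carry no channel->locus map")
    channels = np.flatnonzero(features.channel_locus == locus)
    if channels.size == 0:
        raise ValueError(f"locus {locus} has no channels")
    if band_subset is None:
        bands = np.arange(features.n_bands)
    else:
        bands = np.asarray(band_subset, dtype=np.int64)
        if bands.size == 0:
            raise ValueError("band subset is empty")
        if bands.min() < 0 or bands.max() >= features.n_bands:
            raise ValueError("band subset out of range")
    X = features.values[:, channels][:, :, bands]
    X = X.reshape(features.n_frames, channels.size * bands.size)
    column_map = tuple((int(c), int(b)) for c in channels for b in bands)
    return DesignMatrix(X=np.ascontiguousarray(X), column_map=column_map)


def _as_matrix(X) -> np.ndarray:
    return X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)


def ridge_fit(X, target: np.ndarray, lam: float) -> RidgeModel:
    """Ridge regression on column-standardized predictors.

    Coefficients solve (X~'X~ + lam I) b = X~'(y - y_mean) on standardized
    columns and are mapped back to the original scale; lam = 0 is ordinary
    least squares and raises on a rank-deficient system.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    A = _as_matrix(X)
    n, p = A.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    y = np.asarray(target, dtype=float)
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    zero_var = sd == 0
    if lam == 0 and np.any(zero_var):
        raise np.linalg.LinAlgError(
            "constant predictor column makes OLS singular; use lam > 0"
        )
    sd_safe = np.where(zero_var, 1.0, sd)
    Z = (A - mu) / sd_safe
    G = Z.T @ Z + lam * np.eye(p)
    if lam == 0:
        if np.linalg.matrix_rank(G, hermitian=True) < p:
            raise np.linalg.LinAlgError(
                "rank-deficient design with lam = 0; use lam > 0"
            )
    ybar = y.mean()
    b_std = np.linalg.solve(G, Z.T @ (y - ybar))
    b = b_std / sd_safe
    b[zero_var] = 0.0
    intercept = ybar - mu @ b
    return RidgeModel(b=b, intercept=float(intercept), lam=float(lam))


def make_fold_plan(n_frames: int, n_folds: int) -> FoldPlan:
    """Contiguous equal-size blocks in time (limits train/validation leakage)."""
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if n_folds > n_frames:
        raise ValueError("more folds than frames")
    assignment = np.repeat(
        np.arange(n_folds),
        np.diff(np.linspace(0, n_frames, n_folds + 1).astype(np.int64)),
    )
    return FoldPlan(n_folds=n_folds, assignment=assignment)


def cv_predict(X, target: np.ndarray, plan: FoldPlan, lam: float) -> np.ndarray:
    """Out-of-fold predictions: each frame predicted by a model that never saw it.

    A single-fold plan degenerates to refit-on-all (in-sample) prediction.
    """
    A = _as_matrix(X)
    y = np.asarray(target, dtype=float)
    if plan.assignment.size != A.shape[0]:
        raise ValueError("fold plan does not match the number of frames")
    if plan.n_folds == 1:
        return ridge_fit(A, y, lam).predict(A)
    pred = np.empty(A.shape[0])
    for fold in range(plan.n_folds):
        test = plan.assignment == fold
        if not test.any():
            raise ValueError(f"fold {fold} is empty")
        train = ~test
        model = ridge_fit(A[train], y[train], lam)
        pred[test] = model.predict(A[test])
    return pred


def cv_mpc(X, ev: EventTrain, shift: float, folds, lam: float) -> float:
    """Cross-validated MPC at one shift.

    Truncates x(t) and y(t - shift) to their overlap, computes out-of-fold
    ridge predictions there, and returns their Pearson correlation with the
    shifted event train. The sign is retained: out-of-fold R can be negative.
    ``folds`` is a fold count (plan built on the overlap) or a FoldPlan over
    the full frame range, restricted to the overlap.
    """
    A = _as_matrix(X)
    n = A.shape[0]
    sx, sy = _overlap(n, _lag_of(shift, ev.step))
    A_o = A[sx]
    y_o = ev.y[sy].astype(float)
    if y_o.std() == 0:
        raise DegenerateInputError(
            f"shifted event train is constant on the overlap at shift {shift:g}"
        )
    if isinstance(folds, FoldPlan):
        sub = folds.assignment[sx]
        present = np.unique(sub)
        if present.size < folds.n_folds:
            raise ValueError("fold plan has empty folds on the overlap")
        plan = FoldPlan(n_folds=folds.n_folds,
                        assignment=np.searchsorted(present, sub))
    else:
        plan = make_fold_plan(A_o.shape[0], int(folds))
    pred = cv_predict(A_o, y_o, plan, lam)
    if pred.std() == 0:
        return 0.0
    return _pearson(pred, y_o)


def default_shift_grid(step: float, tau_min: float = 0.0,
                       tau_max: float = 1.5) -> np.ndarray:
    """Shift grid in steps equal to the feature step, spanning [tau_min, tau_max]."""
    k_min = int(np.ceil(tau_min / step - 1e-9))
    k_max = int(np.floor(tau_max / step + 1e-9))
    return np.arange(k_min, k_max + 1) * step


def msa_map(features: TFFeatures, ev: EventTrain, shifts=None,
            n_folds: int = 4, lam: float = 1.0) -> MPCMap:
    """Cross-validated shifted MPC curve for every sensor locus.

    Loci are processed independently; a locus whose features are degenerate
    yields a NaN (flagged) curve rather than failing the whole map.
    """
    if features.channel_locus is None:
        raise ValueError("features carry no channel->locus map")
    if shifts is None:
        shifts = default_shift_grid(features.step)
    shifts = np.asarray(shifts, dtype=float)
    loci = np.unique(features.channel_locus)
    values = np.full((loci.size, shifts.size), np.nan)
    degenerate = np.zeros(loci.size, dtype=bool)
    for li, locus in enumerate(loci):
        X = build_design_matrix(features, int(locus))
        for si, tau in enumerate(shifts):
            try:
                values[li, si] = cv_mpc(X, ev, tau, n_folds, lam)
            except (DegenerateInputError, np.linalg.LinAlgError):
                degenerate[li] = True
    return MPCMap(shifts=shifts, values=values, degenerate=degenerate,
                  n_folds=n_folds, lam=lam)
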