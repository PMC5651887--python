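"""PCA -> QDA classification with leave-one-out cross-validation and ROC.

PCA (mean-centered, no variance scaling) is applied to the 890-950 cm^-1
channel slice; the first two scores feed a quadratic discriminant with
per-class Gaussian densities, refit from scratch in every leave-one-out
fold.  ROC analysis with Youden's J selects an operating threshold, either
on the 900/940 band-area ratio (default) or on the held-out QDA posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RamanPipelineError
from .io_formats import LabeledCohort

DEFAULT_REGION = (890.0, 950.0)
POSITIVE = "pregnant"


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Mean + orthonormal loadings for a channel region."""

    mean: np.ndarray
    components: np.ndarray  # (k, n_channels)
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.components.T


def region_matrix(
    cohort: LabeledCohort, lo: float = 890.0, hi: float = 950.0
) -> np.ndarray:
    """Channel slice [lo, hi) of the cohort intensity matrix, manifest order."""
    if cohort.common_axis is None:
        raise RamanPipelineError("cohort has no common axis")
    axis = cohort.common_axis
    mask = (axis >= lo) & (axis < hi)
    if not mask.any():
        raise RamanPipelineError(
            f"region [{lo}, {hi}) lies outside the axis "
            f"[{axis[0]}, {axis[-1]}] or is empty"
        )
    return cohort.intensity_matrix()[:, mask]


def pca_fit(X: np.ndarray, k: int = 2) -> tuple[PCAModel, np.ndarray]:
    """Mean-centered PCA via SVD; returns the model and the top-k scores.

    No variance scaling.  Sign convention: each loading's largest-magnitude
    element is positive.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise RamanPipelineError(f"PCA needs >= {k + 1} samples, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    if rank < k:
        raise RamanPipelineError(f"matrix rank {rank} < requested components {k}")
    comps = Vt[:k]
    # sign convention
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    var = S**2 / np.sum(S**2)
    model = PCAModel(mean, comps, var[:k])
    return model, Xc @ comps.T


# ---------------------------------------------------------------------------
# QDA


@dataclass
class QDAModel:
    """Two-class Gaussian quadratic discriminant on PC scores.

    Class covariances (denominator n_c - 1) are regularized by adding
    lambda * (trace/2) * I, keeping them positive-definite at small n.
    """

    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    priors: dict[str, float]
    regularization: float

    def _log_density(self, cls: str, pts: np.ndarray) -> np.ndarray:
        mu = self.means[cls]
        cov = self.covariances[cls]
        d = mu.size
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise RamanPipelineError(f"covariance for {cls!r} not positive-definite")
        diff = np.atleast_2d(pts) - mu
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.sum(diff * sol, axis=1)
        return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)

    def posterior(self, pts: np.ndarray) -> np.ndarray:
        """P(pregnant | score point) for each row of pts."""
        pts = np.atleast_2d(pts)
        logs = {
            c: self._log_density(c, pts) + np.log(self.priors[c])
            for c in self.means
        }
        keys = list(logs)
        stacked = np.vstack([logs[c] for c in keys])
        stacked -= stacked.max(axis=0, keepdims=True)
        dens = np.exp(stacked)
        post = dens / dens.sum(axis=0, keepdims=True)
        return post[keys.index(POSITIVE)]

    def predict(self, pts: np.ndarray) -> np.ndarray:
        """Class with larger posterior; exact tie goes to nonpregnant."""
        return self.posterior(pts) > 0.5


def qda_fit(scores: np.ndarray, labels, regularization: float = 1e-6) -> QDAModel:
    """Per-class mean/covariance QDA with empirical priors.

    ``labels`` is a boolean array (True = pregnant) or an array of the two
    label strings.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels == POSITIVE
    if scores.shape[0] != labels.size:
        raise RamanPipelineError("scores and labels length mismatch")
    means, covs, priors = {}, {}, {}
    d = scores.shape[1]
    for cls, mask in (("pregnant", labels), ("nonpregnant", ~labels)):
        n_c = int(mask.sum())
        if n_c < 3:
            raise RamanPipelineError(
                f"class {cls!r} has {n_c} samples; need >= 3 for a 2x2 covariance"
            )
        pts = scores[mask]
        means[cls] = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1).reshape(d, d)
        cov = cov + regularization * (np.trace(cov) / 2.0) * np.eye(d)
        covs[cls] = cov
        priors[cls] = n_c / labels.size
    return QDAModel(means, covs, priors, regularization)


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    rule: str = "youden"
    flipped: bool = False
    degenerate: bool = False

    @property
    def optimal_sensitivity(self) -> float:
        i = int(np.argmin(np.abs(self.thresholds - self.optimal_threshold)))
        return float(self.sensitivity[i])

    @property
    def optimal_specificity(self) -> float:
        i = int(np.argmin(np.abs(self.thresholds - self.optimal_threshold)))
        return float(self.specificity[i])


def roc_analysis(scores, labels, positive_higher: bool | None = None) -> ROCCurve:
    """ROC curve, trapezoid AUC, and Youden-optimal threshold.

    Candidate thresholds sit at midpoints between consecutive distinct
    sorted scores plus outer sentinels; a sample is called positive when its
    (oriented) score exceeds the threshold.  When ``positive_higher`` is
    None the orientation is auto-detected: if the higher-is-positive AUC is
    below 0.5 the score is flipped and the flip flagged.  Youden ties break
    toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels == POSITIVE
    if scores.size != labels.size:
        raise RamanPipelineError("scores and labels length mismatch")
    if not np.all(np.isfinite(scores)):
        raise RamanPipelineError("non-finite scores")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise RamanPipelineError("both classes must be present for ROC analysis")

    def _curve(sc):
        distinct = np.unique(sc)
        if distinct.size == 1:
            thr = np.array([distinct[0] - 1.0, distinct[0] + 1.0])
        else:
            mids = 0.5 * (distinct[:-1] + distinct[1:])
            thr = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
        sens = np.array([np.mean(sc[labels] > t) for t in thr])
        spec = np.array([np.mean(sc[~labels] <= t) for t in thr])
        # trapezoid AUC over (FPR, TPR), FPR increasing
        fpr = 1.0 - spec
        order = np.lexsort((sens, fpr))  # ties at one FPR traversed upward
        auc = float(np.trapezoid(np.concatenate(([0.0], sens[order], [1.0])),
                                 np.concatenate(([0.0], fpr[order], [1.0]))))
        return thr, sens, spec, auc

    flipped = False
    work = scores
    thr, sens, spec, auc = _curve(work)
    if positive_higher is None:
        if auc < 0.5:
            flipped = True
    elif positive_higher is False:
        flipped = True
    if flipped:
        work = -scores
        thr, sens, spec, auc = _curve(work)

    degenerate = np.unique(scores).size == 1
    if degenerate:
        auc = 0.5
    j = sens + spec - 1.0
    best = 0
    for i in range(1, thr.size):
        if j[i] > j[best] + 1e-12:
            best = i
    optimal = float(-thr[best]) if flipped else float(thr[best])
    out_thr = -thr[::-1] if flipped else thr
    out_sens = sens[::-1] if flipped else sens
    out_spec = spec[::-1] if flipped else spec
    return ROCCurve(out_thr, out_sens, out_spec, auc, optimal,
                    flipped=flipped, degenerate=degenerate)


# ---------------------------------------------------------------------------
# confusion metrics and LOOCV


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / n

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


def format_percent(x: float) -> str:
    """Display-time rounding of a percentage.

    Values exact at one decimal are printed as-is (62.5 -> "62.5"); anything
    else rounds to the whole percent (93.333 -> "93").  Fractions are kept
    exact internally; rounding happens only here.
    """
    tenths = x * 10.0
    if abs(tenths - round(tenths)) < 1e-9:
        if abs(x - round(x)) < 1e-9:
            return f"{round(x):d}"
        return f"{x:.1f}"
    return f"{round(x):d}"


def confusion_metrics(predictions, labels) -> ConfusionMetrics:
    """TP/FN/TN/FP with pregnant as the positive class."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.dtype != bool:
        predictions = predictions == POSITIVE
    if labels.dtype != bool:
        labels = labels == POSITIVE
    if predictions.size != labels.size:
        raise RamanPipelineError("prediction/label length mismatch")
    return ConfusionMetrics(
        tp=int(np.sum(predictions & labels)),
        fn=int(np.sum(~predictions & labels)),
        tn=int(np.sum(~predictions & ~labels)),
        fp=int(np.sum(predictions & ~labels)),
    )


@dataclass
class CVResult:
    """Leave-one-out results: held-out scores, predictions, and metrics."""

    sample_ids: list[str]
    labels: np.ndarray  # bool, True = pregnant
    posterior_scores: np.ndarray  # held-out P(pregnant)
    predictions: np.ndarray  # bool
    confusion: ConfusionMetrics
    excluded: dict[str, str] = field(default_factory=dict)
    explained_variance_ratio: np.ndarray | None = None

    @property
    def sensitivity(self) -> float:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float:
        return self.confusion.specificity


def loocv(
    cohort_or_matrix,
    labels=None,
    region: tuple[float, float] = DEFAULT_REGION,
    k: int = 2,
    regularization: float = 1e-6,
    sample_ids: list[str] | None = None,
) -> CVResult:
    """Leave-one-out cross-validated PCA->QDA classification.

    Accepts a preprocessed LabeledCohort (the region slice is taken from its
    common axis) or a raw (samples x channels) matrix plus labels.  PCA and
    QDA are refit on each fold's n-1 training samples, so the held-out
    spectrum never influences its own projection (no leakage).  Posterior
    tie (exactly 0.5) predicts nonpregnant.
    """
    if isinstance(cohort_or_matrix, LabeledCohort):
        X = region_matrix(cohort_or_matrix, *region)
        y = cohort_or_matrix.label_array()
        ids = cohort_or_matrix.sample_ids
    else:
        X = np.asarray(cohort_or_matrix, dtype=float)
        if labels is None:
            raise RamanPipelineError("labels required with a raw matrix")
        y = np.asarray(labels)
        if y.dtype != bool:
            y = y == POSITIVE
        ids = sample_ids or [f"s{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    post = np.full(n, np.nan)
    preds = np.zeros(n, dtype=bool)
    ok = np.zeros(n, dtype=bool)
    excluded: dict[str, str] = {}
    for i in range(n):
        train = np.arange(n) != i
        try:
            model, scores = pca_fit(X[train], k=k)
            qda = qda_fit(scores, y[train], regularization)
            held = model.transform(X[i : i + 1])
            post[i] = float(qda.posterior(held)[0])
            preds[i] = bool(qda.predict(held)[0])
            ok[i] = True
        except RamanPipelineError as exc:
            excluded[ids[i]] = str(exc)
    if not ok.any():
        raise RamanPipelineError("every LOOCV fold failed")
    cm = confusion_metrics(preds[ok], y[ok])
    full_model, _ = pca_fit(X, k=k)
    return CVResult(
        [ids[i] for i in range(n) if ok[i]],
        y[ok],
        post[ok],
        preds[ok],
        cm,
        excluded,
        full_model.explained_variance_ratio,
    )
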