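"""Dynamic connectome-based predictive modeling.

Edges whose connectivity time course correlates with the behavioral target
consistently across training subjects (one-sample t-test on Fisher-z
correlations, p < alpha) are selected as features; a radial-basis
support-vector regression maps the selected edges' connectivity to the
target. Within-dataset accuracy uses leave-one-subject-out cross-validation
— the held-out subject contributes to neither feature selection nor training
— and fold accuracies (Pearson r, RMSE on standardized series) are averaged
on the Fisher-z scale. Across-dataset prediction re-uses the consensus
feature set (edges selected in every fold, with consistent signs) and fits a
single model on all training subjects.

Numerical notes: features are standardized with training-set statistics only;
``train_stride`` optionally thins the *training* samples (step-1 windows
overlap almost completely, so adjacent samples are nearly redundant) while
predictions and scores always use the full TR grid; the SVR is sklearn's
with library-default hyperparameters (C=1, epsilon=0.1, gamma='scale'),
recorded on the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ttest_1samp, ttest_rel
from sklearn.svm import SVR

from .behavior import fisher_mean, zscore
from .dynfc import DynFCSet

__all__ = [
    "FeatureMask",
    "CPMFit",
    "FoldResult",
    "AccuracySummary",
    "LosoResult",
    "select_features",
    "fit_cpm",
    "predict_cpm",
    "fit_predict",
    "score_prediction",
    "run_loso",
    "run_cross_dataset",
    "group_average_prediction",
    "paired_fold_comparison",
]

_R_CLIP = 1.0 - 1e-15


class NoFeaturesError(RuntimeError):
    """Raised when feature selection returns an empty edge set."""


@dataclass(frozen=True)
class FeatureMask:
    """Selected edges and their signs (sign of the mean training correlation)."""

    edges: np.ndarray   # sorted edge ids
    signs: np.ndarray   # +1 / -1 per selected edge
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.edges.shape != self.signs.shape:
            raise ValueError("signs must align with selected edges")

    @property
    def n_edges(self) -> int:
        return int(self.edges.size)

    def positive(self) -> np.ndarray:
        return self.edges[self.signs > 0]

    def negative(self) -> np.ndarray:
        return self.edges[self.signs < 0]


@dataclass
class CPMFit:
    """A trained regressor plus everything needed to apply it elsewhere."""

    mask: FeatureMask
    svr: SVR
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    hyperparams: dict
    edge_hash: str | None = None
    training_ids: tuple[str, ...] = ()


@dataclass
class FoldResult:
    subject_id: str
    prediction: np.ndarray | None
    r: float
    rmse: float
    ok: bool = True


@dataclass
class AccuracySummary:
    """Fold accuracies summarized on the Fisher-z scale."""

    fold_r: np.ndarray
    fold_rmse: np.ndarray
    mean_r: float
    mean_rmse: float
    n_folds: int
    n_failed: int = 0


@dataclass
class LosoResult:
    summary: AccuracySummary
    consensus: FeatureMask
    folds: list[FoldResult]
    fold_masks: list[FeatureMask]


def _as_z(data) -> tuple[np.ndarray, str | None]:
    if isinstance(data, DynFCSet):
        return data.z, data.edge_hash
    return np.asarray(data, dtype=float), None


def _corr_rows(z: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson r of every row of ``z`` (E x T) with ``target``."""
    tc = target - target.mean()
    zc = z - z.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(zc, axis=1) * np.linalg.norm(tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (zc @ tc) / denom
    return np.where(denom > 0, r, 0.0)


def _corr_matrix(z: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-subject, per-edge correlation with the target, shape (S, E)."""
    return np.stack([_corr_rows(z[s], target) for s in range(z.shape[0])])


def _mask_from_vals(vals: np.ndarray, alpha: float) -> FeatureMask:
    """Selection t-test on a (subjects x edges) matrix of transformed correlations."""
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = ttest_1samp(vals, 0.0, axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    sel = np.flatnonzero(p < alpha)
    signs = np.sign(vals.mean(axis=0)[sel]).astype(int)
    keep = signs != 0
    return FeatureMask(edges=sel[keep], signs=signs[keep], alpha=alpha)


def select_features(train, target: np.ndarray, alpha: float = 0.01,
                    fisher_z: bool = True) -> FeatureMask:
    """Edges reliably correlated with the target across training subjects.

    Per subject and edge the Pearson correlation between the edge's
    connectivity series and the target is computed; the (optionally
    Fisher-z transformed) correlations are tested against zero across
    subjects with a two-tailed one-sample t-test, and edges with p < alpha
    are kept. The edge sign is the sign of the mean transformed correlation.
    """
    z, _ = _as_z(train)
    if z.ndim != 3 or z.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    if z.shape[2] != len(target):
        raise ValueError("target length must match the connectivity series")
    rs = _corr_matrix(z, target)
    vals = np.arctanh(np.clip(rs, -_R_CLIP, _R_CLIP)) if fisher_z else rs
    return _mask_from_vals(vals, alpha)


def _default_svr_params() -> dict:
    return {"kernel": "rbf", "C": 1.0, "epsilon": 0.1, "gamma": "scale"}


def fit_cpm(train, target: np.ndarray, mask: FeatureMask, train_stride: int = 1,
            svr_params: dict | None = None, edge_hash: str | None = None,
            training_ids: tuple[str, ...] = ()) -> CPMFit:
    """Fit the SVR on all training subjects' concatenated windows.

    The group target is tiled once per training subject. ``train_stride``
    keeps every k-th TR of the training samples only (the standardization
    statistics are computed on the kept samples).
    """
    z, data_hash = _as_z(train)
    edge_hash = edge_hash or data_hash
    if mask.n_edges == 0:
        raise NoFeaturesError("empty feature mask")
    params = {**_default_svr_params(), **(svr_params or {})}
    sl = slice(None, None, max(int(train_stride), 1))
    feats = np.concatenate([z[s][mask.edges][:, sl].T for s in range(z.shape[0])])
    y = np.tile(np.asarray(target, dtype=float)[sl], z.shape[0])
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    svr = SVR(**params).fit((feats - mean) / sd, y)
    return CPMFit(mask=mask, svr=svr, feat_mean=mean, feat_sd=sd, hyperparams=params,
                  edge_hash=edge_hash, training_ids=tuple(training_ids))


def predict_cpm(fit: CPMFit, test_z: np.ndarray, edge_hash: str | None = None) -> np.ndarray:
    """Predict the target series from one subject's edge-by-time matrix."""
    if fit.edge_hash is not None and edge_hash is not None and fit.edge_hash != edge_hash:
        raise ValueError("edge index hash mismatch between model and test data")
    feats = (np.asarray(test_z, dtype=float)[fit.mask.edges].T - fit.feat_mean) / fit.feat_sd
    return fit.svr.predict(feats)


def fit_predict(train, target: np.ndarray, mask: FeatureMask, test_z: np.ndarray,
                train_stride: int = 1, svr_params: dict | None = None) -> np.ndarray:
    fit = fit_cpm(train, target, mask, train_stride=train_stride, svr_params=svr_params)
    return predict_cpm(fit, test_z)


def score_prediction(pred: np.ndarray, target: np.ndarray,
                     standardize: bool = True) -> tuple[float, float]:
    """(Pearson r, RMSE) of a prediction against the z-scored target.

    By default the prediction is standardized against its own mean and sd
    before the RMSE, putting the error on the same unit-variance scale as
    the target (``standardize=False`` gives the raw-scale RMSE). A constant
    prediction scores r = 0 (flagged by warning) and is treated as an
    all-zero standardized series.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("prediction and target lengths differ")
    if pred.std(ddof=1) == 0:
        warnings.warn("constant prediction; r recorded as 0")
        r, zp = 0.0, np.zeros_like(pred) if standardize else pred
    else:
        r = float(np.corrcoef(pred, target)[0, 1])
        zp = zscore(pred) if standardize else pred
    rmse = float(np.sqrt(np.mean((zp - target) ** 2)))
    return r, rmse


def _summarize(folds: list[FoldResult]) -> AccuracySummary:
    ok = [f for f in folds if f.ok]
    rs = np.array([f.r for f in ok])
    rmses = np.array([f.rmse for f in ok])
    return AccuracySummary(
        fold_r=rs, fold_rmse=rmses,
        mean_r=fisher_mean(rs) if rs.size else float("nan"),
        mean_rmse=float(rmses.mean()) if rmses.size else float("nan"),
        n_folds=len(ok), n_failed=len(folds) - len(ok),
    )


def _consensus(fold_masks: list[FeatureMask], alpha: float) -> FeatureMask:
    """Intersection of fold masks, keeping only sign-consistent edges."""
    common = fold_masks[0].edges
    for m in fold_masks[1:]:
        common = np.intersect1d(common, m.edges)
    keep, signs = [], []
    for e in common:
        s = {int(m.signs[np.searchsorted(m.edges, e)]) for m in fold_masks}
        if len(s) == 1:
            keep.append(e)
            signs.append(s.pop())
        else:
            warnings.warn(f"edge {e} dropped from consensus (conflicting fold signs)")
    return FeatureMask(edges=np.asarray(keep, dtype=np.int64),
                       signs=np.asarray(signs, dtype=int), alpha=alpha)


def run_loso(dataset, target: np.ndarray, alpha: float = 0.01, train_stride: int = 1,
             svr_params: dict | None = None,
             subject_ids: list[str] | None = None) -> LosoResult:
    """Leave-one-subject-out cross-validation of the full select/fit/score loop.

    The held-out subject never enters feature selection or training. The
    consensus mask — edges selected in every fold with a consistent sign —
    is the dataset's "arousal network" and feeds the across-dataset and
    network-anatomy stages.
    """
    z, edge_hash = _as_z(dataset)
    n_sub = z.shape[0]
    if n_sub < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    if subject_ids is None:
        subject_ids = (dataset.subject_ids if isinstance(dataset, DynFCSet)
                       else [f"sub-{s:02d}" for s in range(n_sub)])
    target = np.asarray(target, dtype=float)
    if z.shape[2] != len(target):
        raise ValueError("target length must match the connectivity series")
    params = {**_default_svr_params(), **(svr_params or {})}
    sl = slice(None, None, max(int(train_stride), 1))
    # the per-(subject, edge) selection correlations do not depend on the fold
    vals = np.arctanh(np.clip(_corr_matrix(z, target), -_R_CLIP, _R_CLIP))
    folds: list[FoldResult] = []
    fold_masks: list[FeatureMask] = []
    for held in range(n_sub):
        rows = [s for s in range(n_sub) if s != held]
        mask = _mask_from_vals(vals[rows], alpha)
        fold_masks.append(mask)
        if mask.n_edges == 0:
            warnings.warn(f"fold {subject_ids[held]}: no features selected")
            folds.append(FoldResult(subject_ids[held], None, np.nan, np.nan, ok=False))
            continue
        feats = np.concatenate([z[s][mask.edges][:, sl].T for s in rows])
        y = np.tile(target[sl], n_sub - 1)
        mean = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        svr = SVR(**params).fit((feats - mean) / sd, y)
        fit = CPMFit(mask=mask, svr=svr, feat_mean=mean, feat_sd=sd,
                     hyperparams=params, edge_hash=edge_hash)
        pred = predict_cpm(fit, z[held], edge_hash=edge_hash)
        r, rmse = score_prediction(pred, target)
        folds.append(FoldResult(subject_ids[held], pred, r, rmse))
    return LosoResult(summary=_summarize(folds),
                      consensus=_consensus(fold_masks, alpha),
                      folds=folds, fold_masks=fold_masks)


def run_cross_dataset(train_datasets, train_targets, mask: FeatureMask, test_dataset,
                      test_target: np.ndarray, train_stride: int = 1,
                      svr_params: dict | None = None) -> tuple[AccuracySummary, list[FoldResult]]:
    """Train one model on full dataset(s), score it on every test subject.

    ``train_datasets``/``train_targets`` are parallel lists (a single
    dataset may be passed bare); features come from the training side only.
    Datasets must share the edge index.
    """
    if isinstance(train_datasets, (DynFCSet, np.ndarray)):
        train_datasets, train_targets = [train_datasets], [train_targets]
    if mask.n_edges == 0:
        raise NoFeaturesError("empty feature mask")
    zs, hashes = zip(*(_as_z(d) for d in train_datasets))
    test_z, test_hash = _as_z(test_dataset)
    known = {h for h in (*hashes, test_hash) if h is not None}
    if len(known) > 1:
        raise ValueError("edge index hash mismatch across datasets")
    params = {**_default_svr_params(), **(svr_params or {})}
    sl = slice(None, None, max(int(train_stride), 1))
    feats = np.concatenate([z[s][mask.edges][:, sl].T
                            for z, tgt in zip(zs, train_targets)
                            for s in range(z.shape[0])])
    y = np.concatenate([np.tile(np.asarray(tgt, dtype=float)[sl], z.shape[0])
                        for z, tgt in zip(zs, train_targets)])
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    svr = SVR(**params).fit((feats - mean) / sd, y)
    fit = CPMFit(mask=mask, svr=svr, feat_mean=mean, feat_sd=sd, hyperparams=params,
                 edge_hash=next(iter(known), None))
    folds = []
    for s in range(test_z.shape[0]):
        pred = predict_cpm(fit, test_z[s], edge_hash=test_hash)
        r, rmse = score_prediction(pred, test_target)
        folds.append(FoldResult(f"test-{s:02d}", pred, r, rmse))
    return _summarize(folds), folds


def group_average_prediction(predictions: np.ndarray, target: np.ndarray) -> float:
    """Correlation between the subject-averaged prediction and the group target."""
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    if predictions.shape[0] < 2:
        raise ValueError("need predictions from at least 2 subjects")
    if predictions.shape[1] != len(target):
        raise ValueError("prediction and target lengths differ")
    mean_pred = predictions.mean(axis=0)
    if mean_pred.std(ddof=1) == 0:
        warnings.warn("constant group-average prediction; r recorded as 0")
        return 0.0
    return float(np.corrcoef(mean_pred, target)[0, 1])


def paired_fold_comparison(r_a, r_b) -> tuple[float, float, int]:
    """Paired two-tailed t-test on Fisher-z fold accuracies; returns (t, p, df)."""
    a = np.arctanh(np.clip(np.asarray(r_a, dtype=float), -_R_CLIP, _R_CLIP))
    b = np.arctanh(np.clip(np.asarray(r_b, dtype=float), -_R_CLIP, _R_CLIP))
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired lists with n >= 3")
    if np.std(a - b, ddof=1) == 0:
        if np.allclose(a, b):
            return 0.0, 1.0, a.size - 1
        warnings.warn("zero variance of paired differences; t is infinite")
        return float(np.sign((a - b).mean()) * np.inf), 0.0, a.size - 1
    t, p = ttest_rel(a, b)
    return float(t), float(p), a.size - 1
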