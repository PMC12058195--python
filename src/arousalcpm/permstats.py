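"""Surrogate-data and resampling statistics.

Phase randomization builds surrogate targets with the original amplitude
spectrum but random Fourier phases — preserving autocorrelation while
destroying alignment with the stimulus — and the prediction pipeline is
re-run on each surrogate to form null distributions for the accuracy
summaries. Also here: the permutation p-value convention
p = (1 + #{null >= empirical}) / (1 + N), circular-shift nulls for
correlations between smooth series, two-one-sided equivalence tests, and
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .cpm import fit_cpm, predict_cpm, run_loso, score_prediction, _summarize, FoldResult

__all__ = [
    "NullDistribution",
    "phase_randomize",
    "permutation_pvalue",
    "build_prediction_null",
    "circular_shift_null",
    "equivalence_tost",
    "bh_fdr",
]


@dataclass
class NullDistribution:
    """A permutation null: statistic name, values, and provenance."""

    statistic: str
    values: np.ndarray
    n_perm: int
    seed: int
    mode: str  # phase_randomized | circular_shift | sign_flip | edge_shuffle

    def __post_init__(self) -> None:
        if len(self.values) != self.n_perm:
            raise ValueError("null length must equal n_perm")


def phase_randomize(series: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Surrogate with the exact amplitude spectrum and uniformly random phases.

    DC and (for even lengths) Nyquist bins keep their phase, so the output
    is real and mean-preserving; by Parseval the variance is preserved too.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 4:
        raise ValueError("series too short to phase-randomize")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = np.fft.rfft(series)
    k = len(spec)
    free = slice(1, k - 1 if n % 2 == 0 else k)  # bins whose phase may rotate
    phases = rng.uniform(0, 2 * np.pi, size=len(spec[free]))
    out_spec = spec.copy()
    out_spec[free] = np.abs(spec[free]) * np.exp(1j * phases)
    return np.fft.irfft(out_spec, n=n)


def permutation_pvalue(empirical: float, nulls: np.ndarray, tail: str = "greater") -> float:
    """p = (1 + #{null at least as extreme}) / (1 + N); floor 1/(N+1)."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if tail == "greater":
        count = int(np.sum(nulls >= empirical))
    elif tail == "less":
        count = int(np.sum(nulls <= empirical))
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    return (1 + count) / (1 + nulls.size)


def build_prediction_null(dataset, target: np.ndarray, n_perm: int = 1000, seed: int = 0,
                          mode: str = "within", alpha: float = 0.01, train_stride: int = 1,
                          svr_params: dict | None = None, mask=None, test_dataset=None,
                          test_target: np.ndarray | None = None,
                          randomize_test: bool = False) -> dict[str, NullDistribution]:
    """Nulls for the accuracy summaries by re-running the pipeline on surrogates.

    ``mode='within'``: each iteration phase-randomizes the target and re-runs
    the full leave-one-subject-out loop (selection, training and testing all
    use the same surrogate). Because the model can learn arbitrary features
    aligned with the surrogate and is tested against that same surrogate,
    this null is conservative and its mean sits above zero.

    ``mode='across'``: each iteration re-fits the model (fixed feature
    ``mask``) on the phase-randomized training target and evaluates
    predictions for the test dataset against the true test target — or a
    surrogate of it when ``randomize_test`` is set. Whatever the model picks
    up from the surrogate does not transfer, so this null centers on zero.

    Returns ``{"r": NullDistribution, "rmse": NullDistribution}``.
    """
    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    null_rmse = np.empty(n_perm)
    if mode == "within":
        for it in range(n_perm):
            surr = phase_randomize(target, rng)
            res = run_loso(dataset, surr, alpha=alpha, train_stride=train_stride,
                           svr_params=svr_params)
            null_r[it] = res.summary.mean_r
            null_rmse[it] = res.summary.mean_rmse
    elif mode == "across":
        if mask is None or test_dataset is None or test_target is None:
            raise ValueError("across mode needs mask, test_dataset and test_target")
        from .cpm import _as_z
        test_z, test_hash = _as_z(test_dataset)
        for it in range(n_perm):
            surr = phase_randomize(target, rng)
            eval_target = phase_randomize(test_target, rng) if randomize_test else test_target
            fit = fit_cpm(dataset, surr, mask, train_stride=train_stride,
                          svr_params=svr_params)
            folds = []
            for s in range(test_z.shape[0]):
                pred = predict_cpm(fit, test_z[s], edge_hash=test_hash)
                r, rmse = score_prediction(pred, eval_target)
                folds.append(FoldResult(f"test-{s:02d}", None, r, rmse))
            summ = _summarize(folds)
            null_r[it] = summ.mean_r
            null_rmse[it] = summ.mean_rmse
    else:
        raise ValueError("mode must be 'within' or 'across'")
    return {
        "r": NullDistribution("mean_r", null_r, n_perm, seed, "phase_randomized"),
        "rmse": NullDistribution("mean_rmse", null_rmse, n_perm, seed, "phase_randomized"),
    }


def circular_shift_null(a: np.ndarray, b: np.ndarray, n: int = 1000,
                        seed: int = 0) -> tuple[float, float]:
    """Correlation of two series tested against circular shifts of the second.

    Shifts are nonzero, drawn uniformly — without replacement when ``n``
    meets or exceeds the number of distinct shifts. Returns (r, p), one
    tailed greater.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 10:
        raise ValueError("need equal-length series of length >= 10")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("constant series")
    r_emp = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    distinct = len(b) - 1
    if n >= distinct:
        shifts = np.arange(1, len(b))
    else:
        shifts = rng.choice(np.arange(1, len(b)), size=n, replace=False)
    nulls = np.array([np.corrcoef(a, np.roll(b, int(k)))[0, 1] for k in shifts])
    return r_emp, permutation_pvalue(r_emp, nulls, tail="greater")


def equivalence_tost(values: np.ndarray, bounds: tuple[float, float] = (-0.1, 0.1),
                     fisher_z: bool = True) -> float:
    """Two one-sided t-tests that the mean lies inside ``bounds``.

    ``values`` are per-fold accuracies (correlations); by default both they
    and the bounds move to the Fisher-z scale before testing. The returned p
    is the larger of the two one-sided p-values; small p supports
    equivalence with zero within the bounds.
    """
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("bounds must be finite with lower < upper")
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 values")
    if fisher_z:
        vals = np.arctanh(np.clip(vals, -1 + 1e-15, 1 - 1e-15))
        lo, hi = np.arctanh(lo), np.arctanh(hi)
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero variance")
    se = sd / np.sqrt(vals.size)
    df = vals.size - 1
    p_lower = t_dist.sf((vals.mean() - lo) / se, df)   # H1: mean > lower bound
    p_upper = t_dist.cdf((vals.mean() - hi) / se, df)  # H1: mean < upper bound
    return float(max(p_lower, p_upper))


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (rejection mask, adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj
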