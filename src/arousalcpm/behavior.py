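"""From continuous rating logs to the model target.

Raw slider logs are resampled to one value per TR (last value carried
forward), segments are concatenated and z-scored per rater, the panel is
averaged into a group series, intersubject agreement is quantified by
leave-one-out correlation with a sign-flip permutation test, and the group
series is convolved with a canonical hemodynamic response function and
smoothed with the same tapered sliding window later applied to the
connectivity series. Positivity/negativity segments are extracted from the
raw (un-normalized) group mean around the neutral slider position.

Conventions adopted where the procedure leaves room: the resampled value for
TR k is the slider value prevailing at the *end* of the interval
[k*tr, (k+1)*tr); the target transform order is z-score, then HRF
convolution, then taper smoothing; sample standard deviations use the n-1
denominator; correlations of exactly +/-1 are clipped to +/-(1 - 1e-15)
before the Fisher transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "DatasetSpec",
    "RaterPanel",
    "GroupTarget",
    "IscResult",
    "resample_ratings",
    "normalize_and_concat",
    "group_average",
    "leave_one_out_isc",
    "isc_vs_samplesize",
    "hrf_kernel",
    "convolve_hrf",
    "taper_smooth",
    "build_group_target",
    "extract_valence_segments",
    "zscore",
    "fisher_mean",
]

_R_CLIP = 1.0 - 1e-15


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-score with the n-1 denominator; errors on constant input."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def fisher_mean(r: np.ndarray) -> float:
    """Average correlations on the Fisher-z scale: tanh(mean(atanh(r)))."""
    z = np.arctanh(np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP))
    return float(np.tanh(z.mean()))


@dataclass(frozen=True)
class DatasetSpec:
    """Acquisition and analysis constants of one dataset.

    ``segment_tr`` lists the movie segments' lengths in TRs; series are
    concatenated across segments. ``crop_tr`` lists TR indices (0-based, on
    the concatenated grid) excluded before normalization, e.g. non-movie
    filler segments. ``window_tr``/``taper_sigma_tr`` define the tapered
    sliding window shared by the behavioral target and the connectivity
    series.
    """

    tr_s: float
    segment_tr: tuple[int, ...]
    window_tr: int
    taper_sigma_tr: float = 3.0
    step_tr: int = 1
    rating_scale: tuple[float, float] = (1.0, 25.0)
    neutral: float = 13.0
    crop_tr: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.window_tr < 3:
            raise ValueError("window_tr must be >= 3")
        if not self.rating_scale[0] <= self.neutral <= self.rating_scale[1]:
            raise ValueError("neutral must lie within rating_scale")

    @property
    def n_tr(self) -> int:
        return int(sum(self.segment_tr))

    @classmethod
    def from_window_seconds(cls, tr_s: float, segment_tr: tuple[int, ...],
                            window_s: float, **kw) -> "DatasetSpec":
        """Window length in TRs = round(window_s / tr_s)."""
        return cls(tr_s=tr_s, segment_tr=tuple(segment_tr),
                   window_tr=int(round(window_s / tr_s)), **kw)


@dataclass
class RaterPanel:
    """Per-rater resampled series, raw and z-scored, on a common TR grid."""

    rater_ids: list[str]
    raw: np.ndarray   # (n_raters, n_tr)
    z: np.ndarray     # (n_raters, n_tr)


@dataclass
class GroupTarget:
    """The model target at its three processing stages (all same length)."""

    group: np.ndarray       # mean of z-scored rater series
    convolved: np.ndarray   # after HRF convolution
    smoothed: np.ndarray    # after taper smoothing
    hrf_applied: bool = True
    taper_applied: bool = True


@dataclass
class IscResult:
    """Leave-one-out intersubject correlation summary."""

    per_rater_r: np.ndarray
    mean_r: float           # Fisher-z average of per-rater r
    p: float                # one-tailed sign-flip permutation p
    n_permutations: int


def _resample_one(times: np.ndarray, values: np.ndarray, spec: DatasetSpec) -> np.ndarray:
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    if times[0] > 0:
        raise ValueError("first event must occur at or before t=0 (initial slider position)")
    end = spec.n_tr * spec.tr_s
    if np.any(times > end):
        warnings.warn("rating events beyond the movie end were ignored")
    # value prevailing at the end of each TR interval [k*tr, (k+1)*tr)
    interval_ends = (np.arange(spec.n_tr) + 1) * spec.tr_s
    idx = np.searchsorted(times, interval_ends, side="left") - 1
    return values[idx].astype(float)


def resample_ratings(events: pd.DataFrame, spec: DatasetSpec) -> RaterPanel:
    """Resample slider logs to one value per TR (last value carried forward).

    ``events`` carries columns (rater_id, time_s, value). The z-scored panel
    uses the concatenated, cropped series (see ``DatasetSpec.crop_tr``). A
    rater who never moves the slider carries no signal; their z row is all
    zeros (with a warning) rather than an error.
    """
    if events is None or len(events) == 0:
        raise ValueError("empty rating log")
    keep = np.setdiff1d(np.arange(spec.n_tr), np.asarray(spec.crop_tr, dtype=int))
    ids, raw, z = [], [], []
    for rater_id, grp in events.groupby("rater_id", sort=True):
        series = _resample_one(grp["time_s"].to_numpy(float), grp["value"].to_numpy(float), spec)
        ids.append(str(rater_id))
        raw.append(series[keep])
        if np.ptp(raw[-1]) == 0:
            warnings.warn(f"rater {rater_id} has a constant series; z row set to 0")
            z.append(np.zeros_like(raw[-1]))
        else:
            z.append(zscore(raw[-1]))
    return RaterPanel(rater_ids=ids, raw=np.asarray(raw), z=np.vstack(z))


def normalize_and_concat(segments: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-segment series and z-score across the full length."""
    series = np.concatenate([np.asarray(s, dtype=float) for s in segments])
    if len(np.unique(series)) < 2:
        raise ValueError("degenerate input: fewer than 2 distinct values")
    return zscore(series)


def group_average(panel: RaterPanel) -> np.ndarray:
    """Elementwise mean across raters of the z-scored series."""
    if panel.z.shape[0] < 2:
        raise ValueError("need at least 2 raters")
    return panel.z.mean(axis=0)


def leave_one_out_isc(panel: RaterPanel, n_perm: int = 10000, seed: int = 0) -> IscResult:
    """Each rater's correlation with the leave-one-out group mean.

    Summary = Fisher-z average of the per-rater correlations. Significance:
    each rater's Fisher-z similarity receives a random sign with probability
    one half, the signed values are averaged, and the one-tailed (greater)
    permutation p-value compares the observed mean against this null.
    """
    z = panel.z
    n = z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 raters for leave-one-out ISC")
    total = z.sum(axis=0)
    rs = np.empty(n)
    for i in range(n):
        loo_mean = (total - z[i]) / (n - 1)
        if loo_mean.std(ddof=1) == 0:
            raise ValueError(f"leave-one-out mean constant for rater {panel.rater_ids[i]}")
        rs[i] = np.corrcoef(z[i], loo_mean)[0, 1]
    zs = np.arctanh(np.clip(rs, -_R_CLIP, _R_CLIP))
    observed = zs.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = (signs * zs).mean(axis=1)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return IscResult(per_rater_r=rs, mean_r=float(np.tanh(observed)), p=p,
                     n_permutations=n_perm)


def isc_vs_samplesize(panel: RaterPanel, sizes: list[int], n_boot: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Bootstrap the Fisher-z group ISC at each panel size (with replacement)."""
    n = panel.z.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for k in sizes:
        if k < 2 or k > n:
            raise ValueError(f"size {k} outside [2, {n}]")
        vals = np.empty(n_boot)
        for b in range(n_boot):
            sub = panel.z[rng.integers(0, n, size=k)]
            total = sub.sum(axis=0)
            zs = []
            for i in range(k):
                loo = (total - sub[i]) / (k - 1)
                sd = loo.std(ddof=1)
                r = np.corrcoef(sub[i], loo)[0, 1] if sd > 0 else 0.0
                zs.append(np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)))
            vals[b] = np.mean(zs)
        rows.append({"size": k, "mean_z_isc": vals.mean(), "sd_z_isc": vals.std(ddof=1)})
    return pd.DataFrame(rows)


def hrf_kernel(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR.

    Response gamma with shape 6, undershoot gamma with shape 16 (both unit
    scale, seconds), undershoot ratio 1/6 — the de facto standard; peak near
    5 s.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0, duration_s + tr_s / 2, tr_s)
    h = gamma_dist.pdf(t, a=6.0) - gamma_dist.pdf(t, a=16.0) / 6.0
    return h / h.sum()


def convolve_hrf(series: np.ndarray, tr_s: float) -> np.ndarray:
    """Causal convolution with the canonical HRF, truncated to input length."""
    series = np.asarray(series, dtype=float)
    return np.convolve(series, hrf_kernel(tr_s), mode="full")[: len(series)]


def _window_offsets(window_tr: int) -> np.ndarray:
    # centered window; for even lengths one extra sample on the left
    return np.arange(-(window_tr // 2), window_tr - window_tr // 2)


def taper_weights(center: int, spec: DatasetSpec, series_len: int) -> tuple[np.ndarray, np.ndarray]:
    """In-bounds window indices and Gaussian taper weights (sum 1) at ``center``.

    The Gaussian (sd ``taper_sigma_tr``) is evaluated on the window's TR
    offsets, truncated at the series boundaries, and renormalized.
    """
    if not 0 <= center < series_len:
        raise ValueError("center outside series")
    offs = _window_offsets(spec.window_tr)
    idx = center + offs
    inside = (idx >= 0) & (idx < series_len)
    idx = idx[inside]
    w = np.exp(-0.5 * (offs[inside] / spec.taper_sigma_tr) ** 2)
    return idx, w / w.sum()


def taper_smooth(series: np.ndarray, spec: DatasetSpec) -> np.ndarray:
    """Tapered-sliding-window smoothing: Gaussian-weighted mean at every TR."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    if spec.window_tr > n:
        raise ValueError("window longer than series")
    out = np.empty(n)
    for t in range(n):
        idx, w = taper_weights(t, spec, n)
        out[t] = float(w @ series[idx])
    return out


def build_group_target(panel: RaterPanel, spec: DatasetSpec) -> GroupTarget:
    """Group-average the panel, HRF-convolve, and taper-smooth (in that order)."""
    group = group_average(panel)
    conv = convolve_hrf(group, spec.tr_s)
    smooth = taper_smooth(conv, spec)
    return GroupTarget(group=group, convolved=conv, smoothed=smooth)


def extract_valence_segments(
    raw_group: np.ndarray, spec: DatasetSpec, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """TRs where the raw group mean is above (positive) / below (negative) neutral.

    Returns the retained TR indices and the retained series concatenated in
    order then z-scored, HRF-convolved and taper-smoothed. Ratings exactly at
    the neutral value belong to neither mode. An empty selection returns two
    empty arrays (the caller decides how to proceed).
    """
    raw_group = np.asarray(raw_group, dtype=float)
    if mode == "positive":
        idx = np.flatnonzero(raw_group > spec.neutral)
    elif mode == "negative":
        idx = np.flatnonzero(raw_group < spec.neutral)
    else:
        raise ValueError("mode must be 'positive' or 'negative'")
    if idx.size == 0:
        return idx, np.empty(0)
    if idx.size < spec.window_tr:
        raise ValueError("selected segment shorter than the smoothing window")
    series = zscore(raw_group[idx])
    series = convolve_hrf(series, spec.tr_s)
    return idx, taper_smooth(series, spec)
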