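"""Synthetic multi-subject datasets with a planted arousal-connectivity link.

The generator emulates the statistical structure the downstream analysis
assumes: a smooth latent "arousal" state modulates the instantaneous
correlation of a planted set of ROI pairs in every subject's BOLD-like time
series, while a panel of noisy raters reports the same latent state on a
1-25 slider. Ground truth (the latent series and per-edge target
correlations) is retained so recovery can be measured exactly.

Coupling mechanism
------------------
For a planted edge (i, j) with target correlation ``rho(t)``, both ROIs
receive a shared Gaussian component scaled by ``a(t) =
sqrt(rho(t)/(1-rho(t))) * noise_sd`` on top of independent Gaussian noise of
sd ``noise_sd``; the instantaneous model correlation between the two ROIs is
then exactly ``rho(t)``. The target correlation is ``rho(t) = 0.9 * coupling
* sigmoid(latent(t))``, kept below 0.9 so Fisher-z values stay bounded.
The construction is exact only when planted edges share no ROI; the default
edge picker therefore uses ROI-disjoint pairs.

Reproducibility: one master seed; every stochastic component draws from a
sub-stream keyed by (seed, component, index), so adding subjects or raters
does not perturb existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_planted_edges",
    "generate_latent_state",
    "make_truth",
    "generate_roi_timeseries",
    "generate_raters",
    "generate_nuisance",
    "generate_dataset_pair",
    "make_dataset",
    "write_dataset",
]

# sub-stream identifiers (fixed offsets in the seed hierarchy)
_STREAM_LATENT = 0
_STREAM_SUBJECT = 1
_STREAM_RATER = 2
_STREAM_NUISANCE = 3
_STREAM_FD = 4
_STREAM_PAIR = 5


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for the sub-stream identified by ``key`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design constants of one simulated dataset.

    ``coupling`` is the unitless gain in [0, 1] mapping the latent state to
    the planted edges' target correlation; ``rater_press_rate`` is the
    expected number of slider adjustments per minute.
    """

    n_subjects: int = 16
    n_roi: int = 60
    n_tr: int = 500
    tr_s: float = 1.5
    planted_edges: tuple[tuple[int, int], ...] = ()
    coupling: float = 0.6
    noise_sd: float = 1.0
    n_raters: int = 30
    rater_noise_sd: float = 0.5
    rater_press_rate: float = 12.0
    latent_smoothness_tr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_roi, self.n_tr, self.n_raters) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.rater_press_rate <= 0:
            raise ValueError("rater_press_rate must be positive")
        for i, j in self.planted_edges:
            if not (0 <= i < j < self.n_roi):
                raise ValueError(f"planted edge ({i}, {j}) outside ROI range 0..{self.n_roi - 1}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one dataset: latent state and per-edge target correlations."""

    latent: np.ndarray                         # (n_tr,), mean 0, sample sd 1
    planted_edges: tuple[tuple[int, int], ...]
    rho: np.ndarray                            # (n_edges, n_tr), values in (-1, 1)

    def __post_init__(self) -> None:
        if np.any(np.abs(self.rho) >= 1.0):
            raise ValueError("|rho| must stay below 1")


def default_planted_edges(n_roi: int, n_edges: int, seed: int = 0) -> tuple[tuple[int, int], ...]:
    """ROI-disjoint planted edges, so the coupling construction is exact."""
    if 2 * n_edges > n_roi:
        raise ValueError(f"cannot place {n_edges} ROI-disjoint edges on {n_roi} ROIs")
    rois = _rng(seed, _STREAM_PAIR, 0).permutation(n_roi)[: 2 * n_edges]
    return tuple(tuple(sorted((int(rois[2 * k]), int(rois[2 * k + 1])))) for k in range(n_edges))


def generate_latent_state(n_tr: int, smoothness_tr: float, seed: int) -> np.ndarray:
    """Gaussian white noise convolved with a Gaussian kernel, then standardized.

    ``smoothness_tr`` is the kernel sd in TRs; larger values raise the lag-1
    autocorrelation of the result.
    """
    if n_tr <= 0 or smoothness_tr <= 0:
        raise ValueError("n_tr and smoothness_tr must be positive")
    if n_tr < 10 * smoothness_tr:
        raise ValueError("need n_tr >= 10 * smoothness_tr for a usable latent series")
    rng = _rng(seed, _STREAM_LATENT)
    half = int(np.ceil(4 * smoothness_tr))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / smoothness_tr) ** 2)
    kernel /= kernel.sum()
    white = rng.standard_normal(n_tr + 2 * half)
    latent = np.convolve(white, kernel, mode="valid")[:n_tr]
    latent = latent - latent.mean()
    return latent / latent.std(ddof=1)


def _latent_to_rho(latent: np.ndarray, coupling: float) -> np.ndarray:
    """Target edge correlation: coupling * sigmoid(latent), rescaled to (0, 0.9)."""
    return 0.9 * coupling / (1.0 + np.exp(-latent))


def make_truth(cfg: SyntheticConfig) -> SyntheticTruth:
    latent = generate_latent_state(cfg.n_tr, cfg.latent_smoothness_tr, cfg.seed)
    rho_row = _latent_to_rho(latent, cfg.coupling)
    rho = np.tile(rho_row, (max(len(cfg.planted_edges), 1), 1))
    return SyntheticTruth(latent=latent, planted_edges=cfg.planted_edges, rho=rho)


def generate_roi_timeseries(cfg: SyntheticConfig, truth: SyntheticTruth) -> np.ndarray:
    """Per-subject ROI-by-time matrices, shape (n_subjects, n_roi, n_tr)."""
    if truth.latent.shape[0] != cfg.n_tr:
        raise ValueError("truth inconsistent with config (n_tr mismatch)")
    for i, j in truth.planted_edges:
        if not (0 <= i < j < cfg.n_roi):
            raise ValueError(f"planted edge ({i}, {j}) outside ROI range")
    data = np.empty((cfg.n_subjects, cfg.n_roi, cfg.n_tr))
    for s in range(cfg.n_subjects):
        rng = _rng(cfg.seed, _STREAM_SUBJECT, s)
        x = rng.standard_normal((cfg.n_roi, cfg.n_tr)) * cfg.noise_sd
        for e, (i, j) in enumerate(truth.planted_edges):
            rho = truth.rho[e]
            amp = np.sqrt(rho / (1.0 - rho)) * cfg.noise_sd
            shared = rng.standard_normal(cfg.n_tr) * amp
            x[i] += shared
            x[j] += shared
        data[s] = x
    return data


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def generate_raters(truth: SyntheticTruth, cfg: SyntheticConfig) -> pd.DataFrame:
    """Timestamped slider logs for a panel of raters, columns (rater_id, time_s, value).

    Each rater holds a right-continuous step function: at Poisson-rate press
    times the slider jumps to the latent state rescaled to [1, 25] plus AR(1)
    noise, rounded half-away-from-zero to the integer grid and clipped.
    """
    if cfg.n_raters < 2:
        raise ValueError("need at least 2 raters")
    if cfg.rater_press_rate <= 0:
        raise ValueError("rater_press_rate must be positive")
    lo, hi = 1.0, 25.0
    lat = truth.latent
    span = lat.max() - lat.min()
    scaled = lo + (hi - lo) * (lat - lat.min()) / span  # latent on the slider scale
    duration = cfg.n_tr * cfg.tr_s
    rows = []
    phi = 0.8  # AR(1) persistence of rater noise
    for r in range(cfg.n_raters):
        rng = _rng(cfg.seed, _STREAM_RATER, r)
        # press times: Poisson process, rate per minute -> per second
        rate_s = cfg.rater_press_rate / 60.0
        n_max = int(np.ceil(duration * rate_s + 10 * np.sqrt(duration * rate_s) + 10))
        gaps = rng.exponential(1.0 / rate_s, size=n_max)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        times = times[times < duration]
        noise = 0.0
        for t in times:
            noise = phi * noise + np.sqrt(1 - phi**2) * rng.standard_normal() * cfg.rater_noise_sd
            k = min(int(t / cfg.tr_s), cfg.n_tr - 1)
            value = np.clip(_round_half_away(np.array(scaled[k] + noise)), lo, hi)
            rows.append((f"rater{r:03d}", float(t), int(value)))
    out = pd.DataFrame(rows, columns=["rater_id", "time_s", "value"])
    return out.sort_values(["rater_id", "time_s"], kind="stable").reset_index(drop=True)


def generate_nuisance(
    cfg: SyntheticConfig, leak_latent: np.ndarray | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Ten low-level stimulus feature series plus per-subject framewise displacement.

    Features mirror the usual audio-visual confound list: six continuous
    series (hue, saturation, pixel intensity, motion energy, amplitude,
    pitch) as smoothed standardized noise, and four 0/1 indicators (face,
    indoor, text, music) as persistent two-state Markov chains. FD is
    non-negative with occasional motion spikes. ``leak_latent``, when given,
    replaces the first feature by latent + noise so that confound regression
    measurably removes planted signal (a leakage test mode).
    """
    rng = _rng(cfg.seed, _STREAM_NUISANCE)
    n = cfg.n_tr
    names_cont = ["hue", "saturation", "intensity", "motion_energy", "amplitude", "pitch"]
    names_ind = ["face", "indoor", "text", "music"]
    feats = {}
    kernel = np.exp(-0.5 * (np.arange(-12, 13) / 4.0) ** 2)
    kernel /= kernel.sum()
    for name in names_cont:
        x = np.convolve(rng.standard_normal(n + 24), kernel, mode="valid")[:n]
        feats[name] = (x - x.mean()) / x.std(ddof=1)
    for name in names_ind:
        state = int(rng.integers(2))
        chain = np.empty(n, dtype=int)
        flips = rng.random(n) < 0.05  # persistence 0.95
        for t in range(n):
            if flips[t]:
                state = 1 - state
            chain[t] = state
        feats[name] = chain
    if leak_latent is not None:
        feats[names_cont[0]] = leak_latent + 0.5 * rng.standard_normal(n)
    features = pd.DataFrame(feats)
    fd = np.empty((cfg.n_subjects, n))
    for s in range(cfg.n_subjects):
        r = _rng(cfg.seed, _STREAM_FD, s)
        base = r.gamma(shape=2.0, scale=0.05, size=n)
        spikes = (r.random(n) < 0.02) * r.exponential(0.5, size=n)
        fd[s] = base + spikes
    return features, fd


@dataclass
class SyntheticDataset:
    """Bundle of one simulated dataset: config, truth, BOLD, ratings, nuisance."""

    cfg: SyntheticConfig
    truth: SyntheticTruth
    bold: np.ndarray                  # (n_subjects, n_roi, n_tr)
    ratings: pd.DataFrame             # rater_id, time_s, value
    features: pd.DataFrame            # 10 nuisance series, length n_tr
    fd: np.ndarray                    # (n_subjects, n_tr)


def make_dataset(cfg: SyntheticConfig, with_raters: bool = True) -> SyntheticDataset:
    """Generate a complete dataset from one config (deterministic in cfg.seed)."""
    truth = make_truth(cfg)
    bold = generate_roi_timeseries(cfg, truth)
    ratings = generate_raters(truth, cfg) if with_raters else pd.DataFrame(
        columns=["rater_id", "time_s", "value"]
    )
    features, fd = generate_nuisance(cfg)
    return SyntheticDataset(cfg=cfg, truth=truth, bold=bold, ratings=ratings,
                            features=features, fd=fd)


def generate_dataset_pair(
    cfg_a: SyntheticConfig,
    cfg_b: SyntheticConfig,
    shared_fraction: float,
    seed: int,
    n_planted: int = 20,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Two datasets whose planted edge sets share a controlled fraction.

    ``round(shared_fraction * n_planted)`` edges are common to both datasets;
    the remainder are disjoint between them. The datasets may differ in TR,
    series length and subject count but must agree on ``n_roi``.
    """
    if cfg_a.n_roi != cfg_b.n_roi:
        raise ValueError("datasets must share n_roi to share an edge index")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    n_shared = int(round(shared_fraction * n_planted))
    # one disjoint pool large enough for shared + both datasets' private edges
    pool = default_planted_edges(cfg_a.n_roi, 2 * n_planted - n_shared, seed=seed)
    shared = pool[:n_shared]
    priv_a = pool[n_shared:n_planted]
    priv_b = pool[n_planted : 2 * n_planted - n_shared]
    cfg_a = replace(cfg_a, planted_edges=tuple(shared + priv_a), seed=seed * 2 + 1)
    cfg_b = replace(cfg_b, planted_edges=tuple(shared + priv_b), seed=seed * 2 + 2)
    return make_dataset(cfg_a), make_dataset(cfg_b)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write a dataset in the pipeline's on-disk formats.

    Per-subject ROI matrices as TSV (rows = TRs, columns = ROI labels),
    rating logs as CSV, truth as JSON, FD as single-column CSVs.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = [f"roi{k:03d}" for k in range(ds.cfg.n_roi)]
    for s in range(ds.cfg.n_subjects):
        pd.DataFrame(ds.bold[s].T, columns=labels).to_csv(
            outdir / f"sub-{s:02d}_bold.tsv", sep="\t", index=False
        )
        pd.DataFrame({"fd": ds.fd[s]}).to_csv(outdir / f"sub-{s:02d}_fd.csv", index=False)
    ds.ratings.to_csv(outdir / "ratings.csv", index=False)
    ds.features.to_csv(outdir / "nuisance.csv", index=False)
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "planted_edges": [list(e) for e in ds.truth.planted_edges],
                "latent": ds.truth.latent.tolist(),
            }
        )
    )
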