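"""Tapered sliding-window dynamic functional connectivity and confound removal.

For every pair of ROIs the Fisher-z transformed, Gaussian-weighted Pearson
correlation is computed within a window centered on each TR (step 1 TR),
truncated and renormalized at the series boundaries — so the edge-by-time
matrix has exactly one column per input TR and aligns with the
taper-smoothed behavioral target. Correlations are fully weighted (weighted
means and variances), not computed unweighted on a masked window.

Confound handling follows the two routes the analysis uses: low-level
stimulus features are regressed out of the BOLD series per ROI; framewise
displacement is taper-smoothed with the same window spec and regressed out
of the connectivity series per edge.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .behavior import DatasetSpec, taper_smooth, taper_weights

__all__ = [
    "EdgeIndex",
    "DynFCSet",
    "edge_index",
    "taper_weights",
    "compute_dynfc",
    "compute_dynfc_set",
    "save_dynfc",
    "load_dynfc",
    "regress_confounds_bold",
    "regress_confounds_fc",
]

logger = logging.getLogger(__name__)

_Z_CLIP = 1.0 - 1e-7  # correlation clip before the Fisher transform


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical ordering of ROI pairs: row-major upper triangle, i < j."""

    n_roi: int
    pairs: np.ndarray  # (n_edges, 2) int

    @property
    def n_edges(self) -> int:
        return self.pairs.shape[0]

    @property
    def hash(self) -> str:
        return hashlib.sha1(self.pairs.tobytes() + str(self.n_roi).encode()).hexdigest()

    def lookup(self, i: int, j: int) -> int:
        """Edge id of the pair (i, j)."""
        i, j = (i, j) if i < j else (j, i)
        # row-major upper-triangle offset
        return int(i * self.n_roi - i * (i + 1) // 2 + (j - i - 1))


def edge_index(n_roi: int) -> EdgeIndex:
    if n_roi < 2:
        raise ValueError("need at least 2 ROIs")
    iu = np.triu_indices(n_roi, k=1)
    return EdgeIndex(n_roi=n_roi, pairs=np.column_stack(iu).astype(np.int64))


@dataclass
class DynFCSet:
    """Per-subject edge-by-time Fisher-z connectivity on a shared edge index."""

    z: np.ndarray            # (n_subjects, n_edges, n_tr)
    edges: EdgeIndex
    spec: DatasetSpec
    subject_ids: list[str]

    @property
    def edge_hash(self) -> str:
        return self.edges.hash


def compute_dynfc(roi_ts: np.ndarray, spec: DatasetSpec) -> np.ndarray:
    """Edge-by-time Fisher-z windowed correlations for one subject.

    ``roi_ts`` is ROI x T. For each TR the weighted correlation matrix of the
    taper-windowed data is computed and its upper triangle stored. Windows
    with zero weighted variance yield z = 0 for the affected edges, with the
    count reported through the module logger.
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    n_roi, n_tr = roi_ts.shape
    if n_tr < spec.window_tr:
        raise ValueError("series shorter than the sliding window")
    iu = np.triu_indices(n_roi, k=1)
    out = np.empty((len(iu[0]), n_tr))
    n_degenerate = 0
    for t in range(n_tr):
        idx, w = taper_weights(t, spec, n_tr)
        x = roi_ts[:, idx]
        mu = x @ w
        xc = x - mu[:, None]
        cov = (xc * w) @ xc.T
        sd = np.sqrt(np.diag(cov))
        bad = sd == 0
        if bad.any():
            n_degenerate += int(bad.sum())
            sd = np.where(bad, 1.0, sd)
        r = cov / np.outer(sd, sd)
        if bad.any():
            r[bad, :] = 0.0
            r[:, bad] = 0.0
        out[:, t] = np.arctanh(np.clip(r[iu], -_Z_CLIP, _Z_CLIP))
    if n_degenerate:
        logger.warning("zero weighted variance in %d ROI-window cells; z set to 0",
                       n_degenerate)
    return out


def compute_dynfc_set(bold: np.ndarray, spec: DatasetSpec,
                      subject_ids: list[str] | None = None) -> DynFCSet:
    """Dynamic FC for a stack of subjects, shape (S, R, T) -> (S, E, T)."""
    bold = np.asarray(bold, dtype=float)
    n_sub, n_roi, _ = bold.shape
    edges = edge_index(n_roi)
    z = np.stack([compute_dynfc(bold[s], spec) for s in range(n_sub)])
    if subject_ids is None:
        subject_ids = [f"sub-{s:02d}" for s in range(n_sub)]
    return DynFCSet(z=z, edges=edges, spec=spec, subject_ids=subject_ids)


def save_dynfc(fcset: DynFCSet, outdir) -> None:
    """Write per-subject compressed edge-by-time matrices plus a JSON sidecar.

    The sidecar records the edge-index hash and the window spec, so a later
    load (or another dataset) can be checked for compatibility.
    """
    import dataclasses
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s, sid in enumerate(fcset.subject_ids):
        np.savez_compressed(outdir / f"{sid}_dynfc.npz", z=fcset.z[s])
    (outdir / "dynfc.json").write_text(json.dumps({
        "edge_hash": fcset.edge_hash,
        "n_roi": fcset.edges.n_roi,
        "spec": dataclasses.asdict(fcset.spec),
        "subject_ids": list(fcset.subject_ids),
    }, default=list))


def load_dynfc(outdir) -> DynFCSet:
    """Read a connectivity set written by :func:`save_dynfc`; verifies the hash."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    meta = json.loads((outdir / "dynfc.json").read_text())
    spec_raw = meta["spec"]
    for key in ("segment_tr", "rating_scale", "crop_tr"):
        spec_raw[key] = tuple(spec_raw[key])
    spec = DatasetSpec(**spec_raw)
    edges = edge_index(meta["n_roi"])
    if edges.hash != meta["edge_hash"]:
        raise ValueError("edge index hash mismatch in stored connectivity set")
    z = np.stack([np.load(outdir / f"{sid}_dynfc.npz")["z"]
                  for sid in meta["subject_ids"]])
    return DynFCSet(z=z, edges=edges, spec=spec, subject_ids=list(meta["subject_ids"]))


def _ols_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each row of ``y`` against the columns of ``design``."""
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return y - (design @ beta).T


def _with_intercept(nuisance: np.ndarray) -> np.ndarray:
    """Design matrix [intercept | nuisance^T], collinear columns dropped."""
    design = np.column_stack([np.ones(nuisance.shape[1]), nuisance.T])
    # drop columns that do not increase rank (intercept always kept)
    keep = [0]
    for c in range(1, design.shape[1]):
        trial = design[:, keep + [c]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(c)
    if len(keep) < design.shape[1]:
        warnings.warn(f"dropped {design.shape[1] - len(keep)} collinear nuisance column(s)")
    return design[:, keep]


def regress_confounds_bold(roi_ts: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Per-ROI OLS residuals of the BOLD series against the nuisance series.

    ``nuisance`` is features x T; an intercept is always included, so the
    residuals are demeaned and orthogonal to every nuisance series.
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[1] != roi_ts.shape[1]:
        raise ValueError("nuisance series length must match the BOLD series")
    return _ols_residuals(roi_ts, _with_intercept(nuisance))


def regress_confounds_fc(fc: np.ndarray, fd: np.ndarray, spec: DatasetSpec) -> np.ndarray:
    """Per-edge OLS residuals of the connectivity series against smoothed FD.

    FD is taper-smoothed with the same window spec before regression, since
    the connectivity values it confounds are themselves windowed quantities.
    Constant FD degenerates to demeaning, with a warning.
    """
    fc = np.asarray(fc, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != fc.shape[1]:
        raise ValueError("fd must be aligned to the same TR grid as the FC series")
    smoothed = taper_smooth(fd, spec)
    if np.allclose(smoothed, smoothed[0]):
        warnings.warn("constant framewise displacement; residuals are the demeaned input")
        return fc - fc.mean(axis=1, keepdims=True)
    return _ols_residuals(fc, _with_intercept(smoothed[None, :]))
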