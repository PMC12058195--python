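"""End-to-end orchestration: config, validation, the full pipeline, reporting.

A run goes simulate (or load) -> behavioral target -> dynamic FC -> LOSO
CPM -> phase-randomized null -> network anatomy, writing per-stage outputs
(CSV/JSON) plus a report JSON that carries the config hash, the edge-index
hash, seeds and warning counts. Every stochastic stage draws its seed from
the master seed, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, cpm, dynfc, netanat, permstats, synthetic

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips losslessly via YAML."""

    n_subjects: int = 8
    n_roi: int = 30
    n_tr: int = 250
    tr_s: float = 1.5
    n_planted: int = 8
    coupling: float = 0.6
    n_raters: int = 10
    window_tr: int = 30
    taper_sigma_tr: float = 3.0
    alpha: float = 0.01
    n_perm: int = 100
    enrichment_n_perm: int = 1000
    train_stride: int = 1
    regress_fd: bool = False
    regress_features: bool = False
    window_sweep_s: tuple[float, ...] = ()
    seed: int = 0
    outdir: str = "arousalcpm_run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "window_sweep_s" in raw:
            raw["window_sweep_s"] = tuple(raw["window_sweep_s"])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def _dataset_spec(config: RunConfig, window_tr: int | None = None) -> behavior.DatasetSpec:
    return behavior.DatasetSpec(
        tr_s=config.tr_s, segment_tr=(config.n_tr,),
        window_tr=window_tr or config.window_tr,
        taper_sigma_tr=config.taper_sigma_tr,
    )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Simulate one dataset and run every analysis stage; return the report."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    cfg = synthetic.SyntheticConfig(
        n_subjects=config.n_subjects, n_roi=config.n_roi, n_tr=config.n_tr,
        tr_s=config.tr_s, coupling=config.coupling, n_raters=config.n_raters,
        planted_edges=synthetic.default_planted_edges(
            config.n_roi, config.n_planted, seed=config.seed),
        seed=config.seed,
    )
    ds = synthetic.make_dataset(cfg)
    synthetic.write_dataset(ds, out / "data")

    spec = _dataset_spec(config)
    panel = behavior.resample_ratings(ds.ratings, spec)
    isc = behavior.leave_one_out_isc(panel, n_perm=10000, seed=config.seed + 1)
    target_obj = behavior.build_group_target(panel, spec)
    target = behavior.zscore(target_obj.smoothed)
    _write_json(out / "isc.json", {
        "mean_r": isc.mean_r, "p": isc.p, "n_permutations": isc.n_permutations,
        "per_rater_r": isc.per_rater_r.tolist(),
    })

    bold = ds.bold
    if config.regress_features:
        nuis = ds.features.to_numpy(float).T
        bold = np.stack([dynfc.regress_confounds_bold(b, nuis) for b in bold])
    fcset = dynfc.compute_dynfc_set(bold, spec)
    if config.regress_fd:
        fcset.z = np.stack([
            dynfc.regress_confounds_fc(fcset.z[s], ds.fd[s], spec)
            for s in range(config.n_subjects)
        ])

    loso = cpm.run_loso(fcset, target, alpha=config.alpha,
                        train_stride=config.train_stride)
    pd.DataFrame(
        [{"subject": f.subject_id, "r": f.r, "rmse": f.rmse, "ok": f.ok}
         for f in loso.folds]
    ).to_csv(out / "folds.csv", index=False)

    nulls = permstats.build_prediction_null(
        fcset, target, n_perm=config.n_perm, seed=config.seed + 2, mode="within",
        alpha=config.alpha, train_stride=config.train_stride)
    p_r = permstats.permutation_pvalue(loso.summary.mean_r, nulls["r"].values, "greater")
    p_rmse = permstats.permutation_pvalue(loso.summary.mean_rmse, nulls["rmse"].values, "less")
    pd.DataFrame({"iteration": np.arange(config.n_perm),
                  "r": nulls["r"].values, "rmse": nulls["rmse"].values}
                 ).to_csv(out / "null.csv", index=False)

    assignment = netanat.NetworkAssignment(labels=tuple(
        netanat.CANONICAL_NETWORKS[i % 8] for i in range(config.n_roi)))
    signed = netanat.mask_to_signed_edge_set(loso.consensus, edge_hash=fcset.edge_hash,
                                             source="consensus")
    enrich = {}
    for sign_name, ids in (("positive", signed.positive), ("negative", signed.negative)):
        table = netanat.networkpair_enrichment(
            ids, assignment, fcset.edges, n_perm=config.enrichment_n_perm,
            seed=config.seed + 3, q=0.05)
        table.to_csv(out / f"enrichment_{sign_name}.csv", index=False)
        enrich[sign_name] = int(table["significant"].sum())

    sweep = []
    for window_s in config.window_sweep_s:
        sw_spec = _dataset_spec(config, window_tr=int(round(window_s / config.tr_s)))
        sw_target = behavior.zscore(
            behavior.taper_smooth(target_obj.convolved, sw_spec))
        sw_fc = dynfc.compute_dynfc_set(bold, sw_spec)
        sw = cpm.run_loso(sw_fc, sw_target, alpha=config.alpha,
                          train_stride=config.train_stride)
        sweep.append({"window_s": window_s, "mean_r": sw.summary.mean_r,
                      "mean_rmse": sw.summary.mean_rmse})

    report = {
        "config_hash": config.config_hash,
        "edge_hash": fcset.edge_hash,
        "seed": config.seed,
        "isc": {"mean_r": isc.mean_r, "p": isc.p},
        "loso": {"mean_r": loso.summary.mean_r, "mean_rmse": loso.summary.mean_rmse,
                 "n_folds": loso.summary.n_folds, "n_failed": loso.summary.n_failed,
                 "p_r": p_r, "p_rmse": p_rmse},
        "consensus_edges": {"positive": len(signed.positive),
                            "negative": len(signed.negative)},
        "enrichment_significant_pairs": enrich,
        "window_sweep": sweep,
        "runtime_s": round(time.time() - t0, 2),
    }
    _write_json(out / "report.json", report)
    logger.info("pipeline finished in %.1f s", report["runtime_s"])
    return report


def validate_inputs(data_dir, spec: behavior.DatasetSpec | None = None,
                    n_roi: int | None = None) -> dict:
    """Check an input directory's matrices, rating ranges and shapes.

    Returns {"errors": [...], "warnings": [...]}; never raises on bad data.
    """
    data_dir = Path(data_dir)
    errors: list[str] = []
    warnings_: list[str] = []
    bold_files = sorted(data_dir.glob("sub-*_bold.tsv"))
    if not bold_files:
        errors.append(f"no subject BOLD matrices (sub-*_bold.tsv) in {data_dir}")
    shapes = {}
    for f in bold_files:
        try:
            df = pd.read_csv(f, sep="\t")
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            errors.append(f"{f.name}: unreadable ({exc})")
            continue
        shapes[f.name] = df.shape
        if n_roi is not None and df.shape[1] != n_roi:
            errors.append(f"{f.name}: expected {n_roi} ROI columns, found {df.shape[1]}")
        if spec is not None and df.shape[0] != spec.n_tr:
            errors.append(f"{f.name}: expected {spec.n_tr} TR rows, found {df.shape[0]}")
    if len({s[1] for s in shapes.values()}) > 1:
        errors.append("subjects disagree on ROI count: "
                      + ", ".join(f"{k}={v[1]}" for k, v in shapes.items()))
    ratings_path = data_dir / "ratings.csv"
    if ratings_path.exists():
        ratings = pd.read_csv(ratings_path)
        missing = {"rater_id", "time_s", "value"} - set(ratings.columns)
        if missing:
            errors.append(f"ratings.csv missing column(s): {sorted(missing)}")
        else:
            bad = ratings[(ratings["value"] < 1) | (ratings["value"] > 25)]
            if len(bad):
                errors.append(f"ratings.csv: {len(bad)} value(s) outside [1, 25]")
            if (ratings["time_s"] < 0).any():
                errors.append("ratings.csv: negative timestamps")
    else:
        warnings_.append("no ratings.csv found")
    return {"errors": errors, "warnings": warnings_}
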