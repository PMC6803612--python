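"""End-to-end orchestration: phantom -> segmentation -> features -> statistics
-> signatures, driven by a single configuration object (or YAML file).

``run_pipeline`` produces a reproducible bundle in the output directory:

* ``features.csv`` — per-patient conventional PET metrics plus the 38
  radiomic features per modality;
* ``feature_comparison.csv`` — Wilcoxon screening with BH-FDR flags;
* ``spearman_r.csv`` / ``spearman_p.csv`` — PET radiomic vs conventional
  metric rank correlations;
* ``per_feature_roc.csv`` — whole-cohort oriented AUC per feature with the
  Noether test;
* ``signature_results.csv`` (+ ``.json``) — cross-validated performance of
  every requested signature scope, with and without clinical covariates;
* ``manifest.json`` — every analysis parameter actually applied, plus seed
  and package versions, for audit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (
    FEATURE_NAMES,
    GLCM_ANGLES_DEG,
    GLCM_DISTANCE,
    GLDS_DISPLACEMENTS,
    GRAY_LEVELS,
    extract_feature_vector,
)
from .image_io import read_cohort_table, read_volume_pair, write_feature_table
from .pet_metrics import METRIC_NAMES, compute_conventional_metrics
from .phantom import PhantomConfig, SyntheticCohort, generate_cohort
from .segmentation import MTV_CUTOFF_SUV, RELATIVE_THRESHOLD, segment_isocontour
from .signature import SignatureSpec, combine_with_clinical, evaluate_signature
from .stats import FDR_Q, compare_features, per_feature_roc, spearman_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_report", "build_manifest",
           "extract_cohort_features"]


@dataclass
class RunConfig:
    out_dir: str = "petrad_run"
    seed: int = 0
    input_dir: str | None = None  # pre-generated cohort; None -> phantom
    phantom: dict = field(default_factory=dict)
    relative_threshold: float = RELATIVE_THRESHOLD
    mtv_cutoff: float = MTV_CUTOFF_SUV
    slice_mode: str = "largest"
    gray_levels: int = GRAY_LEVELS
    fdr_q: float = FDR_Q
    scopes: tuple[str, ...] = ("petct", "pet", "ct")
    include_clinical: tuple[bool, ...] = (False, True)
    folds: int = 10
    repeats: int = 10
    n_rounds: int = 100
    max_depth: int = 1
    make_plots: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.scopes = tuple(cfg.scopes)
        cfg.include_clinical = tuple(cfg.include_clinical)
        return cfg


def build_manifest(config: RunConfig) -> dict:
    """The applied-parameter manifest: one authoritative record per run."""
    return {
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "segmentation": {
            "relative_threshold": config.relative_threshold,
            "mtv_cutoff_suv": config.mtv_cutoff,
            "connectivity_3d": 26,
        },
        "features": {
            "n_features_per_modality": len(FEATURE_NAMES),
            "gray_levels": config.gray_levels,
            "glcm": {
                "angles_deg": list(GLCM_ANGLES_DEG),
                "distance_px": GLCM_DISTANCE,
            },
            "glds": {"displacements": [list(d) for d in GLDS_DISPLACEMENTS]},
            "slice_mode": config.slice_mode,
        },
        "stats": {"fdr_q": config.fdr_q},
        "signature": {
            "cv_folds": config.folds,
            "cv_repeats": config.repeats,
            "boosting_rounds": config.n_rounds,
            "tree_depth": config.max_depth,
            "scopes": list(config.scopes),
        },
    }


def _load_cohort(input_dir: Path) -> SyntheticCohort:
    table = read_cohort_table(input_dir / "cohort.csv")
    seeds = pd.read_csv(input_dir / "seed_points.csv").set_index("patient_id")
    volumes, truth = [], []
    for _, row in table.iterrows():
        pid = row["patient_id"]
        pair = read_volume_pair(
            input_dir / f"{pid}_pet.nii.gz", input_dir / f"{pid}_ct.nii.gz", row
        )
        volumes.append(pair)
        s = seeds.loc[pid]
        truth.append(
            {"patient_id": pid, "label": row["egfr_label"],
             "seed_point": (int(s["seed_z"]), int(s["seed_y"]), int(s["seed_x"]))}
        )
    return SyntheticCohort(volumes=volumes, cohort_table=table, truth=truth)


def extract_cohort_features(cohort: SyntheticCohort, config: RunConfig) -> pd.DataFrame:
    """Segment every lesion and assemble the per-patient feature matrix.

    Columns: the five conventional PET metrics, then ``pet_<feature>`` and
    ``ct_<feature>`` in the fixed 38-feature order.
    """
    rows = []
    for pair, t in zip(cohort.volumes, cohort.truth):
        roi = segment_isocontour(
            pair.pet,
            t["seed_point"],
            relative_threshold=config.relative_threshold,
            mtv_cutoff=config.mtv_cutoff,
        )
        metrics = compute_conventional_metrics(pair.pet, roi, pair.spacing)
        row: dict[str, float] = dict(metrics.as_dict())
        for modality in ("pet", "ct"):
            vec = extract_feature_vector(
                pair, roi, modality,
                slice_mode=config.slice_mode, gray_levels=config.gray_levels,
            )
            row.update({f"{modality}_{k}": v for k, v in vec.items()})
        rows.append(pd.Series(row, name=pair.patient_id))
    return pd.DataFrame(rows)


def _scope_columns(scope: str, columns) -> list[str]:
    if scope == "pet":
        return [c for c in columns if c.startswith("pet_")]
    if scope == "ct":
        return [c for c in columns if c.startswith("ct_")]
    if scope == "petct":
        return [c for c in columns if c.startswith(("pet_", "ct_"))]
    if scope == "clinical":
        return []
    raise ValueError(f"unknown scope {scope!r}")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns artifact paths."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = build_manifest(config)

    if config.input_dir is not None:
        logger.info("loading cohort from %s", config.input_dir)
        cohort = _load_cohort(Path(config.input_dir))
    else:
        phantom_cfg = PhantomConfig(**{**config.phantom, "seed": config.seed})
        manifest["phantom"] = {
            "n_mutant": phantom_cfg.n_mutant,
            "n_wild": phantom_cfg.n_wild,
            "grid_shape": list(phantom_cfg.grid_shape),
            "voxel_spacing_mm": list(phantom_cfg.voxel_spacing),
        }
        logger.info(
            "generating phantom cohort: %d mutant / %d wild",
            phantom_cfg.n_mutant, phantom_cfg.n_wild,
        )
        cohort = generate_cohort(phantom_cfg)

    features = extract_cohort_features(cohort, config)
    labels = cohort.cohort_table["egfr_label"].to_numpy()

    paths: dict[str, Path] = {}
    paths["features"] = out / "features.csv"
    write_feature_table(features, paths["features"])

    comparison = compare_features(features, labels, q=config.fdr_q)
    paths["feature_comparison"] = out / "feature_comparison.csv"
    comparison.to_csv(paths["feature_comparison"], index=False)

    pet_cols = [c for c in features.columns if c.startswith("pet_")]
    r, p = spearman_matrix(features[pet_cols], features[METRIC_NAMES])
    paths["spearman_r"] = out / "spearman_r.csv"
    paths["spearman_p"] = out / "spearman_p.csv"
    r.to_csv(paths["spearman_r"])
    p.to_csv(paths["spearman_p"])

    roc_table = per_feature_roc(features, labels)
    paths["per_feature_roc"] = out / "per_feature_roc.csv"
    roc_table.to_csv(paths["per_feature_roc"], index=False)

    sig_rows = []
    for scope in config.scopes:
        for clinical in config.include_clinical:
            cols = _scope_columns(scope, features.columns)
            X = features[cols]
            if clinical or scope == "clinical":
                X = combine_with_clinical(X, cohort.cohort_table)
            spec = SignatureSpec(
                feature_scope=scope,
                include_clinical=clinical,
                folds=config.folds,
                repeats=config.repeats,
                n_rounds=config.n_rounds,
                max_depth=config.max_depth,
                seed=config.seed,
            )
            logger.info("evaluating signature scope=%s clinical=%s", scope, clinical)
            result = evaluate_signature(X, labels, spec)
            sig_rows.append(
                {"scope": scope, "clinical": clinical, **result.summary_row()}
            )
    sig_table = pd.DataFrame(sig_rows)
    paths["signature_results"] = out / "signature_results.csv"
    sig_table.to_csv(paths["signature_results"], index=False)
    (out / "signature_results.json").write_text(
        json.dumps(sig_rows, indent=2, default=float)
    )

    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def render_report(bundle_dir, make_plots: bool = False) -> Path:
    """Human-readable summary of a completed run bundle."""
    bundle_dir = Path(bundle_dir)
    required = ["features.csv", "feature_comparison.csv", "signature_results.csv",
                "manifest.json"]
    missing = [f for f in required if not (bundle_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"bundle incomplete, missing: {missing}")

    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    sig = pd.read_csv(bundle_dir / "signature_results.csv")
    comparison = pd.read_csv(bundle_dir / "feature_comparison.csv")

    lines = [
        "PET/CT radiomic signature report",
        "=" * 40,
        f"seed: {manifest['seed']}",
        f"gray levels: {manifest['features']['gray_levels']}; "
        f"GLCM angles: {manifest['features']['glcm']['angles_deg']} at distance "
        f"{manifest['features']['glcm']['distance_px']} px",
        f"CV: {manifest['signature']['cv_folds']}-fold x "
        f"{manifest['signature']['cv_repeats']} repeats",
        "",
        f"features significant after BH-FDR: "
        f"{int(comparison['reject'].sum())} / {len(comparison)}",
        "",
    ]
    if len(sig) == 0:
        lines.append("no signatures evaluated")
    else:
        lines.append("signature performance (means over repeats):")
        lines.append(
            f"{'scope':<10}{'clinical':<10}{'AUC':<8}{'acc %':<9}{'sens':<7}{'spec':<7}"
        )
        for _, row in sig.iterrows():
            lines.append(
                f"{row['scope']:<10}{str(bool(row['clinical'])):<10}"
                f"{row['auc']:<8.3f}{row['accuracy_pct']:<9.2f}"
                f"{row['sensitivity']:<7.3f}{row['specificity']:<7.3f}"
            )
    report_path = bundle_dir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")

    if make_plots and len(sig):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        labels = [
            f"{s}{'+clin' if c else ''}" for s, c in zip(sig["scope"], sig["clinical"])
        ]
        ax.bar(labels, sig["auc"])
        ax.set_ylabel("cross-validated AUC")
        ax.set_ylim(0.0, 1.0)
        ax.axhline(0.5, color="gray", ls="--", lw=0.8)
        fig.tight_layout()
        fig.savefig(bundle_dir / "signature_auc.png", dpi=120)
        plt.close(fig)
    return report_path
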