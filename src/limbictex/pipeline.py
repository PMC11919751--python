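"""Stage orchestration: extract → normalize → select → stats → rmcorr.

Every run writes tidy CSVs plus a serialized copy of its configuration and
a log, so a rerun with the same inputs and seed reproduces the outputs
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .glszm import FEATURE_NAMES, glszm_features
from .image_io import (
    DEFAULT_ROI_REGISTRY,
    DegenerateROIError,
    extract_roi,
    read_registry,
    read_segmentation,
    read_volume,
    roi_volume,
)
from .normalization import HealthyReferenceScaler, PCAFeatureSelector
from .stats import run_stats_stage
from .synthetic import SyntheticCohort

__all__ = ["PipelineConfig", "extract_stage", "run_pipeline"]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = (
    "subject_id", "group", "timepoint", "image_path", "seg_path",
    "age", "sex", "oz_dose", "etiv",
    "panss_total", "panss_pos", "panss_neg", "panss_gen", "cgi_s",
)


@dataclass
class PipelineConfig:
    """Validated run configuration; a copy is written into every output dir."""

    manifest: str = "manifest.csv"
    registry: str | None = None  # TSV path; None -> built-in 14-ROI registry
    out_dir: str = "limbictex_out"
    n_bins: int = 16
    connectivity: int = 26
    min_voxels: int = 10
    var_threshold: float = 0.90
    alpha: float = 0.05
    method: str = "mixed"
    covariates: tuple[str, ...] = ("age", "sex", "oz_dose")
    volume_covariates: tuple[str, ...] = ("age", "sex", "oz_dose", "etiv")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0 < self.var_threshold <= 1:
            raise ValueError("var_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "volume_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["volume_covariates"] = list(self.volume_covariates)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _load_manifest(path: str) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group", "timepoint") if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    return manifest


def extract_stage(
    manifest: pd.DataFrame,
    registry: dict[int, str] | None = None,
    cohort: SyntheticCohort | None = None,
    n_bins: int = 16,
    connectivity: int = 26,
    min_voxels: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (scan, ROI): all 16 GLSZM features and the gray-matter volume.

    Images are read from the manifest's paths, or taken from an in-memory
    synthetic cohort when one is passed. Returns two long tables (texture,
    volume) keyed by subject, group, timepoint, roi.
    """
    registry = dict(registry) if registry is not None else dict(DEFAULT_ROI_REGISTRY)
    tex_rows, vol_rows = [], []
    for _, row in manifest.iterrows():
        sid, tp = row["subject_id"], row["timepoint"]
        if cohort is not None and cohort.images is not None:
            vol, seg = cohort.images[(sid, tp)]
            seg = dataclasses.replace(seg, registry=registry)
        else:
            for col in ("image_path", "seg_path"):
                if col not in row or not isinstance(row[col], str) or not os.path.exists(row[col]):
                    raise FileNotFoundError(
                        f"subject {sid} ({tp}): missing {col} "
                        f"{row.get(col, '<absent>')!r}"
                    )
            vol = read_volume(row["image_path"])
            seg = read_segmentation(row["seg_path"], registry=registry)
        for code, roi_name in registry.items():
            try:
                sample = extract_roi(vol, seg, code, min_voxels=min_voxels)
            except DegenerateROIError as exc:
                raise DegenerateROIError(f"subject {sid} ({tp}): {exc}") from exc
            feats = glszm_features(sample, n_bins=n_bins, connectivity=connectivity)
            base = {"subject_id": sid, "group": row["group"], "timepoint": tp,
                    "roi": roi_name}
            for fname in FEATURE_NAMES:
                tex_rows.append({**base, "feature": fname, "value": feats[fname]})
            vol_rows.append({**base, "feature": "volume",
                             "value": roi_volume(seg, code, min_voxels=min_voxels)})
    return pd.DataFrame(tex_rows), pd.DataFrame(vol_rows)


def _interaction_report(results: dict[str, pd.DataFrame],
                         texture: pd.DataFrame, volumes: pd.DataFrame,
                         alpha: float) -> str:
    """Markdown report of significant group×time interactions, per outcome."""

    def _summaries(table: pd.DataFrame, roi: str, feat: str) -> dict[str, str]:
        sub = table[(table["roi"] == roi) & (table["feature"] == feat)]
        wide = sub.pivot_table(index=["subject_id", "group"], columns="timepoint",
                               values="value", aggfunc="first").reset_index()
        out = {}
        for grp in ("ECT", "MED"):
            g = wide[wide["group"] == grp]
            base = g["baseline"]
            change = g["followup"] - g["baseline"]
            out[f"{grp}_baseline"] = f"{base.mean():.2f} ({base.std(ddof=1):.2f})"
            out[f"{grp}_change"] = f"{change.mean():.2f} ({change.std(ddof=1):.2f})"
        return out

    lines = ["# Group–time interactions (significant after FDR)", ""]
    for label, key, table in (("Texture", "texture", texture), ("Volume (mm³)", "volume", volumes)):
        res = results[key]
        sig = res[res["p_fdr"] < alpha].sort_values("p_fdr")
        lines += [f"## {label}", ""]
        if sig.empty:
            lines += ["No ROI reached significance after FDR correction.", ""]
            continue
        lines += [
            "| ROI | Outcome | ECT baseline | MED baseline | ECT change | MED change | p-FDR |",
            "|---|---|---|---|---|---|---|",
        ]
        for _, r in sig.iterrows():
            s = _summaries(table, r["roi"], r["outcome"])
            lines.append(
                f"| {r['roi']} | {r['outcome']} | {s['ECT_baseline']} | {s['MED_baseline']} "
                f"| {s['ECT_change']} | {s['MED_change']} | {r['p_fdr']:.3g} |"
            )
        lines.append("")
    rm = results.get("rmcorr")
    if rm is not None and len(rm):
        lines += ["## Repeated-measures correlations (significant texture hits vs clinical)", "",
                  "| ROI | Feature | Group | Clinical | r | df | p | p-FDR |",
                  "|---|---|---|---|---|---|---|---|"]
        for _, r in rm.iterrows():
            lines.append(
                f"| {r['roi']} | {r['feature']} | {r['group']} | {r['clinical_var']} "
                f"| {r['r']:.3f} | {r['df']} | {r['p']:.3g} | {r['p_fdr']:.3g} |"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(
    config: PipelineConfig,
    manifest: pd.DataFrame | None = None,
    cohort: SyntheticCohort | None = None,
) -> dict:
    """Execute extract → normalize → select → stats on one cohort.

    Outputs written to ``config.out_dir``: texture_features.csv,
    volumes.csv, reference_stats.csv, normalized_texture.csv,
    selection_report.csv, interactions_texture.csv,
    interactions_volume.csv, rmcorr.csv, report.md, config.yaml, run.log.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("limbictex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("limbictex %s starting, seed=%d", __version__, config.seed)
        config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
        if manifest is None:
            manifest = _load_manifest(config.manifest)
        if cohort is not None and cohort.manifest is not None and manifest is None:
            manifest = cohort.manifest
        registry = (
            read_registry(config.registry) if config.registry else dict(DEFAULT_ROI_REGISTRY)
        )
        if cohort is not None:
            registry = dict(cohort.registry)

        logger.info("extract stage: %d scans x %d ROIs", len(manifest), len(registry))
        texture, volumes = extract_stage(
            manifest, registry=registry, cohort=cohort,
            n_bins=config.n_bins, connectivity=config.connectivity,
            min_voxels=config.min_voxels,
        )

        hc_baseline = texture[(texture["group"] == "HC") & (texture["timepoint"] == "baseline")]
        if hc_baseline.empty:
            raise ValueError("normalize stage: no HC baseline rows in the cohort")
        scaler = HealthyReferenceScaler().fit(hc_baseline)
        normalized = scaler.transform(texture)

        selector = PCAFeatureSelector(var_threshold=config.var_threshold).fit(
            scaler.transform(hc_baseline)
        )
        logger.info(
            "select stage: %d components (cum. var %.3f) -> %s",
            selector.n_components_,
            float(selector.explained_variance_ratio_[: selector.n_components_].sum()),
            selector.selected_features_,
        )

        results = run_stats_stage(
            normalized, volumes, clinical=manifest,
            selected_features=selector.selected_features_,
            covariates=config.covariates,
            volume_covariates=config.volume_covariates,
            alpha=config.alpha, method=config.method,
        )

        out = os.path.join
        texture.to_csv(out(config.out_dir, "texture_features.csv"), index=False)
        volumes.to_csv(out(config.out_dir, "volumes.csv"), index=False)
        scaler.stats_.to_csv(out(config.out_dir, "reference_stats.csv"))
        normalized.to_csv(out(config.out_dir, "normalized_texture.csv"), index=False)
        selector.report().to_csv(out(config.out_dir, "selection_report.csv"))
        results["texture"].to_csv(out(config.out_dir, "interactions_texture.csv"), index=False)
        results["volume"].to_csv(out(config.out_dir, "interactions_volume.csv"), index=False)
        results["rmcorr"].to_csv(out(config.out_dir, "rmcorr.csv"), index=False)
        report = _interaction_report(results, normalized, volumes, config.alpha)
        with open(out(config.out_dir, "report.md"), "w") as fh:
            fh.write(report)
        with open(out(config.out_dir, "selection.json"), "w") as fh:
            json.dump(
                {
                    "n_components": int(selector.n_components_),
                    "selected_features": selector.selected_features_,
                    "explained_variance_ratio": [
                        float(v) for v in selector.explained_variance_ratio_
                    ],
                },
                fh, indent=1,
            )
        logger.info("pipeline complete: outputs in %s", config.out_dir)
        return {
            "texture": texture, "volumes": volumes, "normalized": normalized,
            "scaler": scaler, "selector": selector, "results": results,
        }
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
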