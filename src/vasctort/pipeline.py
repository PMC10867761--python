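"""End-to-end pipeline: mask directory → per-image tortuosity → group report.

``RunConfig`` gathers every knob of the pipeline, rejects unknown keys, and
hashes canonically into every output table so that any two runs differing in
any configuration value are distinguishable from their outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import group_stats, ratios
from .errors import ConfigError, ValidationError
from .mask_io import (
    BinaryMask,
    DiscCenter,
    load_disc_centers,
    load_group_table,
    load_mask,
    write_results_table,
)
from .skeleton_graph import (
    build_vessel_graph,
    exclude_disc_region,
    extract_segments,
    skeletonize_mask,
)
from .tortuosity import (
    TortuosityConfig,
    TortuosityResult,
    image_tortuosity,
    segment_tortuosity,
)

__all__ = [
    "RunConfig",
    "compute_image_tortuosity",
    "run_tortuosity",
    "run_full_experiment",
]

logger = logging.getLogger(__name__)

MASK_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; hashed into every output table."""

    threshold: int = 1
    xy_order: bool = False
    disc_radius_px: float = 50.0
    spur_length_px: float = 10.0
    min_length_px: float = 20.0
    spacing_px: float = 5.0
    smoothing_window: int = 21
    cti_formula: str = "arc_chord"
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        # delegate metric-knob validation
        self.tortuosity_config()
        if self.disc_radius_px < 0 or self.spur_length_px < 0 or self.min_length_px < 0:
            raise ConfigError("lengths/radii must be >= 0")
        if self.threshold < 1:
            raise ConfigError("threshold must be >= 1")

    def tortuosity_config(self) -> TortuosityConfig:
        return TortuosityConfig(
            spacing_px=self.spacing_px,
            smoothing_window=self.smoothing_window,
            cti_formula=self.cti_formula,
            aggregate=self.aggregate,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def compute_image_tortuosity(
    mask: BinaryMask, disc: DiscCenter, config: RunConfig | None = None
) -> TortuosityResult:
    """Run the full tortuosity chain on one mask.

    Skeletonize → pixel graph → disc exclusion → spur pruning and segment
    extraction → per-segment CTI/IC/OC → image means.
    """
    cfg = config or RunConfig()
    disc.validate_against(mask)
    skel = skeletonize_mask(mask)
    graph = build_vessel_graph(skel)
    graph = exclude_disc_region(graph, disc, cfg.disc_radius_px)
    segments = extract_segments(
        graph, disc, min_length_px=cfg.min_length_px, spur_length_px=cfg.spur_length_px
    )
    tcfg = cfg.tortuosity_config()
    seg_metrics = [segment_tortuosity(s, tcfg) for s in segments]
    return image_tortuosity(seg_metrics, mask.image_id, tcfg)


def _discover_masks(mask_dir: Path) -> dict[str, Path]:
    found = {}
    for path in sorted(mask_dir.iterdir()):
        if path.suffix.lower() in MASK_SUFFIXES:
            found[path.stem] = path
    return found


def run_tortuosity(
    mask_dir: str | Path,
    disc_csv: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    per_segment: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Process every mask in a directory; returns (per-image table,
    per-segment table, error messages for images that failed).

    Every mask must have a disc-center record; a missing record aborts with
    a :class:`ValidationError` listing the affected image ids before any
    image is processed.
    """
    cfg = config or RunConfig()
    mask_dir = Path(mask_dir)
    paths = _discover_masks(mask_dir)
    if not paths:
        raise ValidationError(f"no mask files found in {mask_dir}")
    discs = {d.image_id: d for d in load_disc_centers(disc_csv, xy_order=cfg.xy_order)}
    missing = sorted(set(paths) - set(discs))
    if missing:
        raise ValidationError(f"no disc-center record for image_ids: {missing}")

    image_rows, segment_rows, errors = [], [], []
    for image_id, path in paths.items():
        try:
            mask = load_mask(path, threshold=cfg.threshold, image_id=image_id)
            result = compute_image_tortuosity(mask, discs[image_id], cfg)
        except (ValidationError, OSError) as exc:
            errors.append(f"{image_id}: {exc}")
            logger.error("image %s failed: %s", image_id, exc)
            continue
        image_rows.append(
            {
                "image_id": image_id,
                "n_segments": result.n_segments,
                "cti": result.cti,
                "ic": result.ic,
                "oc": result.oc,
                "config_hash": cfg.config_hash,
            }
        )
        for s in result.segments:
            segment_rows.append(
                {
                    "image_id": image_id,
                    "segment_id": s.segment_id,
                    "cti": s.cti,
                    "ic": s.ic,
                    "oc": s.oc,
                    "arc_length_px": s.arc_length_px,
                    "flagged": s.flagged,
                    "config_hash": cfg.config_hash,
                }
            )
    per_image = pd.DataFrame(image_rows)
    per_seg = pd.DataFrame(segment_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if image_rows:
            write_results_table(image_rows, out_dir / "tortuosity_per_image.csv")
        if per_segment and segment_rows:
            write_results_table(segment_rows, out_dir / "tortuosity_per_segment.csv")
        if errors:
            (out_dir / "errors.txt").write_text("\n".join(errors) + "\n")
    return per_image, per_seg, errors


def _pathology_ratios(
    image_id: str,
    shape_mask: BinaryMask,
    nv_dir: Path | None,
    vo_dir: Path | None,
    cfg: RunConfig,
) -> dict[str, float | None]:
    out: dict[str, float | None] = {"nv_ratio": None, "vo_ratio": None}
    for key, folder in (("nv_ratio", nv_dir), ("vo_ratio", vo_dir)):
        if folder is None:
            continue
        candidates = [folder / f"{image_id}{s}" for s in MASK_SUFFIXES]
        hits = [p for p in candidates if p.exists()]
        if not hits:
            continue
        pathology = load_mask(hits[0], threshold=cfg.threshold, image_id=image_id)
        out[key] = ratios.area_ratio(pathology)
    return out


def run_full_experiment(
    mask_dir: str | Path,
    disc_csv: str | Path,
    group_csv: str | Path,
    nv_dir: str | Path | None = None,
    vo_dir: str | Path | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tortuosity + optional NV/VO ratios + group comparisons with stars.

    Returns a tidy per-image table (image_id, condition, timepoint,
    nv_ratio, vo_ratio, cti, ...) and a comparison table with one row per
    (metric, timepoint) contrast across conditions.
    """
    cfg = config or RunConfig()
    groups = load_group_table(group_csv)
    per_image, _, errors = run_tortuosity(mask_dir, disc_csv, cfg, out_dir=None)
    if per_image.empty:
        raise ValidationError(f"no image produced a result; errors: {errors}")
    missing = sorted(set(per_image["image_id"]) - set(groups["image_id"]))
    if missing:
        raise ValidationError(f"image_ids missing from group table: {missing}")

    nv_dir = Path(nv_dir) if nv_dir is not None else None
    vo_dir = Path(vo_dir) if vo_dir is not None else None
    ratio_rows = []
    mask_paths = _discover_masks(Path(mask_dir))
    for image_id in per_image["image_id"]:
        mask = load_mask(mask_paths[image_id], threshold=cfg.threshold, image_id=image_id)
        ratio_rows.append(
            {"image_id": image_id, **_pathology_ratios(image_id, mask, nv_dir, vo_dir, cfg)}
        )
    tidy = (
        per_image.merge(pd.DataFrame(ratio_rows), on="image_id")
        .merge(groups, on="image_id")
    )
    if "timepoint" not in tidy.columns:
        tidy["timepoint"] = "all"
    front = ["image_id", "condition", "timepoint", "nv_ratio", "vo_ratio", "cti"]
    tidy = tidy[front + [c for c in tidy.columns if c not in front]]

    comparison_rows = []
    for metric in ("cti", "ic", "oc", "nv_ratio", "vo_ratio"):
        if tidy[metric].isna().all():
            continue
        for tp, sub in tidy.groupby("timepoint"):
            by_cond = {
                cond: s[metric].dropna().tolist()
                for cond, s in sub.groupby("condition")
            }
            by_cond = {k: v for k, v in by_cond.items() if len(v) >= 2}
            if len(by_cond) < 2:
                continue
            cmp = group_stats.compare(by_cond, metric=metric)
            row = {
                "metric": metric,
                "timepoint": tp,
                "test": cmp.test,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "stars": cmp.stars,
                "config_hash": cfg.config_hash,
            }
            for g in cmp.groups:
                row[f"mean_{g.label}"] = g.mean
                row[f"sd_{g.label}"] = g.sd
                row[f"n_{g.label}"] = g.n
            comparison_rows.append(row)
    comparisons = pd.DataFrame(comparison_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tidy_out = tidy.copy()
        tidy_out["config_hash"] = cfg.config_hash
        tidy_out.to_csv(out_dir / "experiment_per_image.csv", index=False)
        comparisons.to_csv(out_dir / "experiment_comparisons.csv", index=False)
        if errors:
            (out_dir / "errors.txt").write_text("\n".join(errors) + "\n")
    return tidy, comparisons
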