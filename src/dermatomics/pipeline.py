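"""End-to-end orchestration with reproducible configuration.

:func:`run_pipeline` drives slices -> segmentation -> skeleton graph ->
features over a set of input images, appending to a cumulative feature CSV
and emitting per-slice QC overlays plus a run manifest. Every run writes its
fully resolved configuration as JSON next to the outputs, and per-component
accept/reject decisions are logged so silent slice rejection never happens.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dermatomics import morphometrics, segmentation, skeleton, wsi

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline thresholds in one serializable place."""

    site: str = "buttock"
    working_factor: float = 16.0
    min_component_px: int = 50_000
    min_midline_px: int = 500
    od_floor: float = 0.2
    min_object_px: int = 64
    smoothing_sigma: float = 2.0
    hue_range_255: bool = False
    boundary_scope: str = "tissue-boundary"  # or "epidermal-boundary"
    px_per_mm: float | None = None
    seed: int = 0
    out_dir: str = "dermatomics_out"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def process_slice(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    cfg: RunConfig,
    accession_id: str,
    slice_id: int = 0,
) -> tuple[morphometrics.SliceFeatureRecord | None, list[dict]]:
    """Segment one slice crop, analyze each epidermal component, aggregate.

    Returns the feature record (None when every component was rejected) and
    a per-component accept/reject log.
    """
    color_cfg = segmentation.ColorFilterConfig.for_site(
        cfg.site,
        smoothing_sigma=cfg.smoothing_sigma,
        hue_range_255=cfg.hue_range_255,
    )
    epi = segmentation.segment_epidermis(
        image,
        color_cfg,
        tissue_mask=tissue_mask,
        od_floor=cfg.od_floor,
        min_object_px=cfg.min_object_px,
    )
    if cfg.boundary_scope == "epidermal-boundary":
        validation_boundary = skeleton.BoundaryIndex(epi.mask, scope=cfg.boundary_scope)
    else:
        validation_boundary = skeleton.BoundaryIndex(tissue_mask, scope=cfg.boundary_scope)
    components: list[tuple[skeleton.EpidermisGraph, np.ndarray]] = []
    log: list[dict] = []
    for label in range(1, epi.n_components + 1):
        comp = epi.component_mask(label)
        graph = skeleton.analyze_component(
            comp, validation_boundary, cfg.min_midline_px, component_id=label
        )
        components.append((graph, comp))
        log.append(
            {
                "accession_id": accession_id,
                "slice_id": slice_id,
                "component": label,
                "accepted": bool(graph.accepted),
                "reason": graph.rejection_reason,
                "midline_px": graph.midline_length,
                "n_valid_ridges": len(graph.valid_ridges),
            }
        )
    record = morphometrics.slice_features(components, accession_id, slice_id)
    return record, log


def _qc_overlay(image: np.ndarray, components) -> np.ndarray:
    """Midline in blue, valid ridges in green, rejected ridges in red."""
    overlay = image.copy()
    for graph, _ in components:
        if not graph.accepted:
            continue
        mid = graph.midline_pixels()
        if len(mid):
            overlay[mid[:, 0], mid[:, 1]] = (40, 80, 255)
        for ridge in graph.ridges:
            color = (
                (60, 220, 60)
                if ridge.status is skeleton.RidgeStatus.VALID
                else (230, 40, 40)
            )
            px = ridge.branch.pixels
            overlay[px[:, 0], px[:, 1]] = color
    return overlay


def run_pipeline(
    inputs: list[str | Path],
    cfg: RunConfig | None = None,
    write_outputs: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline over input images.

    Returns the cumulative feature table and the run manifest. Per-slice
    failures are recorded and the run continues; callers treat an all-failed
    run as an error condition.
    """
    cfg = cfg or RunConfig()
    out_dir = Path(cfg.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "run_config.json").write_text(cfg.to_json())
    records: list[morphometrics.SliceFeatureRecord] = []
    manifest: dict = {
        "config_hash": cfg.config_hash,
        "schema_version": SCHEMA_VERSION,
        "inputs": [str(p) for p in inputs],
        "slices": [],
        "component_log": [],
        "errors": [],
    }
    for path in inputs:
        accession = Path(path).stem
        try:
            pyr = wsi.load_pyramid(path)
            working = wsi.working_image(pyr, cfg.working_factor)
            tissue = wsi.detect_tissue(
                working, cfg.min_component_px, cfg.working_factor
            )
            slices = wsi.extract_slices(pyr, tissue)
        except Exception as exc:  # noqa: BLE001 - per-input fault isolation
            logger.exception("failed reading %s", path)
            manifest["errors"].append({"input": str(path), "error": str(exc)})
            continue
        for sl in slices:
            try:
                record, log = process_slice(
                    sl.image, sl.mask, cfg, accession, sl.slice_id
                )
            except Exception as exc:  # noqa: BLE001
                logger.exception("slice %s/%s failed", accession, sl.slice_id)
                manifest["errors"].append(
                    {"input": str(path), "slice_id": sl.slice_id, "error": str(exc)}
                )
                continue
            manifest["component_log"].extend(log)
            manifest["slices"].append(
                {
                    "accession_id": accession,
                    "slice_id": sl.slice_id,
                    "bbox_downsampled": list(sl.bbox_downsampled),
                    "bbox_level1": list(sl.bbox_level1),
                    "component_area": sl.component_area,
                    "has_record": record is not None,
                }
            )
            if record is not None:
                records.append(record)
    table = morphometrics.records_to_frame(records)
    if len(table):
        table.insert(0, "schema_version", SCHEMA_VERSION)
        table = table.sort_values(["ID", "slice_id"], kind="stable").reset_index(
            drop=True
        )
    if write_outputs:
        table.to_csv(out_dir / "features.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table, manifest
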