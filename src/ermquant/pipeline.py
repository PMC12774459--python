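"""End-to-end run configuration and orchestration.

A run takes a detection set (and optionally a thickness map and a
ratings table), builds the EPI, quantifies the ERM area/ratio, scores
the ERM-thickness association and, when ratings are present, computes
the observer-agreement battery.  All artifacts (PNG mask, JSON reports)
land in the configured output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as eio
from .association import association_score, class_weights, max_association_score
from .epi_projection import ScanGeometry, build_epi
from .quantification import Calibration, quantify
from .thickness import N_CLASSES, THICKNESS_MAX_UM, THICKNESS_MIN_UM, discretize

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("ermquant")


@dataclass
class RunConfig:
    """Validated configuration for one end-to-end run."""

    detections: str
    out_dir: str
    dialect: str = "json"
    thickness_map: str | None = None
    ratings: str | None = None
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    calibration: Calibration = field(default_factory=Calibration)
    min_confidence: float = 0.25
    thickness_min_um: float = THICKNESS_MIN_UM
    thickness_max_um: float = THICKNESS_MAX_UM
    n_classes: int = N_CLASSES
    accept_threshold: int = 4
    erm_class_id: int = 0

    def __post_init__(self) -> None:
        if self.dialect not in ("json", "yolo_txt"):
            raise ValueError(f"dialect must be 'json' or 'yolo_txt', got {self.dialect!r}")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in [0, 1]")
        if self.thickness_min_um >= self.thickness_max_um:
            raise ValueError("thickness_min_um must be below thickness_max_um")
        if self.n_classes != N_CLASSES:
            raise ValueError(
                f"the association score is defined for {N_CLASSES} thickness classes"
            )
        if not 2 <= self.accept_threshold <= 5:
            raise ValueError("accept_threshold must be in {2..5}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "geometry" in data and isinstance(data["geometry"], dict):
            data["geometry"] = ScanGeometry.from_dict(data["geometry"])
        if "calibration" in data and isinstance(data["calibration"], dict):
            data["calibration"] = Calibration(um_per_pixel=data["calibration"]["um_per_pixel"])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute projection → quantification → association (→ agreement).

    Returns the combined result dict, which is also written to
    ``out_dir/run.json`` alongside the individual artifacts.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    w_sum = float(class_weights().sum())
    logger.info(
        "geometry=%s calibration=%s um/px min_confidence=%s",
        config.geometry.to_dict(),
        config.calibration.um_per_pixel,
        config.min_confidence,
    )
    logger.info(
        "class weights sum to %.3f (score ceiling %.5f), as the weight "
        "polynomial prescribes; they are not renormalized to 1",
        w_sum,
        max_association_score(),
    )

    try:
        detections, geometry = eio.read_detections(
            config.detections,
            dialect=config.dialect,
            geometry=config.geometry,
            erm_class_id=config.erm_class_id,
        )
    except Exception as exc:
        raise RuntimeError(f"[projection] reading detections failed: {exc}") from exc
    epi = build_epi(detections, geometry, min_confidence=config.min_confidence)
    eio.write_epi(epi, out_dir / "epi.png", min_confidence=config.min_confidence)

    report = quantify(epi, config.calibration, geometry)
    eio.write_json(report.to_dict(), out_dir / "area.json")
    results: dict = {
        "geometry": geometry.to_dict(),
        "calibration": config.calibration.to_dict(),
        "min_confidence": config.min_confidence,
        "n_detections_used": sum(
            1 for d in detections if d.confidence >= config.min_confidence
        ),
        "area": report.to_dict(),
        "weights_sum": w_sum,
    }

    if config.thickness_map is not None:
        try:
            tmap = eio.read_thickness_map(config.thickness_map, geometry)
            classes = discretize(
                tmap,
                t_min=config.thickness_min_um,
                t_max=config.thickness_max_um,
                n_classes=config.n_classes,
            )
            assoc = association_score(epi, classes)
        except Exception as exc:
            raise RuntimeError(f"[association] stage failed: {exc}") from exc
        payload = assoc.to_dict()
        payload["class_pixel_counts"] = classes.pixel_counts()
        eio.write_json(payload, out_dir / "association.json")
        results["association"] = payload

    if config.ratings is not None:
        try:
            from .agreement import agreement_report

            study = eio.read_ratings_csv(config.ratings, config.accept_threshold)
            agreement = agreement_report(study)
        except Exception as exc:
            raise RuntimeError(f"[agreement] stage failed: {exc}") from exc
        eio.write_json(agreement.to_dict(), out_dir / "agreement.json")
        (out_dir / "agreement.txt").write_text(agreement.to_text() + "\n")
        results["agreement"] = agreement.to_dict()

    eio.write_json(results, out_dir / "run.json")
    return results
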