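"""Readers and writers for detections, masks, thickness maps and ratings.

Two detection dialects are supported:

* ``yolo_txt`` — a directory of one text file per B-scan, named
  ``{orientation}_{index:02d}.txt``, each line
  ``class x_center y_center width height [confidence]`` with all
  geometric fields normalized to [0, 1].
* ``json`` — a single manifest with a geometry block and a list of
  detection records in B-scan pixels.

EPI masks are written as 8-bit PNG (0/255) with a JSON sidecar carrying
geometry and provenance; thickness maps as CSV matrices or
single-channel TIFF (value = μm, NaN = unmeasured); observer ratings as
a CSV with a ``case_id`` column plus one column per rater.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .agreement import ObserverStudy
from .epi_projection import BScanDetection, EPIMask, Orientation, ScanGeometry
from .thickness import ThicknessMap

__all__ = [
    "DetectionParseError",
    "read_detections",
    "write_detections_json",
    "write_detections_yolo",
    "write_epi",
    "read_epi",
    "read_thickness_map",
    "write_thickness_map",
    "read_ratings_csv",
    "write_ratings_csv",
    "write_json",
]


class DetectionParseError(ValueError):
    """Malformed detection input, with file/line context in the message."""


def _parse_yolo_line(
    line: str,
    lineno: int,
    path: Path,
    scan_index: int,
    orientation: Orientation,
    geometry: ScanGeometry,
    erm_class_id: int,
) -> BScanDetection | None:
    fields = line.split()
    if len(fields) not in (5, 6):
        raise DetectionParseError(
            f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}"
        )
    try:
        cls = int(float(fields[0]))
        xc, yc, w, h = (float(v) for v in fields[1:5])
        conf = float(fields[5]) if len(fields) == 6 else 1.0
    except ValueError as exc:
        raise DetectionParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    for name, v in (("x_center", xc), ("y_center", yc), ("width", w), ("height", h)):
        if not 0.0 <= v <= 1.0:
            raise DetectionParseError(
                f"{path}:{lineno}: {name}={v} outside normalized range [0, 1]"
            )
    if not 0.0 <= conf <= 1.0:
        raise DetectionParseError(f"{path}:{lineno}: confidence={conf} outside [0, 1]")
    if cls != erm_class_id:
        return None
    # boxes may poke slightly past the frame edge; clamp to the B-scan
    x0 = max(0.0, xc - w / 2) * geometry.bscan_width
    x1 = min(1.0, xc + w / 2) * geometry.bscan_width
    if x1 <= x0:
        raise DetectionParseError(f"{path}:{lineno}: box has no width inside the frame")
    return BScanDetection(
        scan_index=scan_index, orientation=orientation, x0=x0, x1=x1, confidence=conf
    )


def _read_yolo_dir(
    directory: Path, geometry: ScanGeometry, erm_class_id: int
) -> list[BScanDetection]:
    detections: list[BScanDetection] = []
    files = sorted(directory.glob("*.txt"))
    if not files:
        raise DetectionParseError(f"no .txt detection files found under {directory}")
    for path in files:
        stem = path.stem
        try:
            orient_str, idx_str = stem.rsplit("_", 1)
            orientation = Orientation(orient_str)
            scan_index = int(idx_str)
        except (ValueError, KeyError):
            raise DetectionParseError(
                f"{path}: file name must be '{{orientation}}_{{index:02d}}.txt'"
            ) from None
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            det = _parse_yolo_line(
                line, lineno, path, scan_index, orientation, geometry, erm_class_id
            )
            if det is not None:
                detections.append(det)
    return detections


def read_detections(
    path: str | Path,
    dialect: str = "json",
    geometry: ScanGeometry | None = None,
    erm_class_id: int = 0,
) -> tuple[list[BScanDetection], ScanGeometry]:
    """Read detections; returns (detections, geometry).

    For ``yolo_txt`` the geometry must be supplied (the files carry only
    normalized coordinates); for ``json`` the manifest's geometry block
    is used unless an explicit one is given.
    """
    path = Path(path)
    if dialect == "yolo_txt":
        geometry = geometry or ScanGeometry()
        return _read_yolo_dir(path, geometry, erm_class_id), geometry
    if dialect == "json":
        data = json.loads(path.read_text())
        geometry = geometry or ScanGeometry.from_dict(data["geometry"])
        detections = [
            BScanDetection(
                scan_index=int(rec["scan_index"]),
                orientation=Orientation(rec["orientation"]),
                x0=float(rec["x0_px"]),
                x1=float(rec["x1_px"]),
                confidence=float(rec.get("confidence", 1.0)),
            )
            for rec in data["detections"]
        ]
        return detections, geometry
    raise ValueError(f"unknown detection dialect {dialect!r}")


def write_detections_json(
    detections: list[BScanDetection],
    geometry: ScanGeometry,
    path: str | Path,
) -> None:
    payload = {
        "geometry": geometry.to_dict(),
        "detections": [
            {
                "orientation": det.orientation.value,
                "scan_index": det.scan_index,
                "x0_px": det.x0,
                "x1_px": det.x1,
                "confidence": det.confidence,
            }
            for det in detections
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_detections_yolo(
    detections: list[BScanDetection],
    geometry: ScanGeometry,
    directory: str | Path,
    erm_class_id: int = 0,
) -> None:
    """Write one YOLO txt per scan (files for empty scans included)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_scan: dict[tuple[str, int], list[BScanDetection]] = {}
    for det in detections:
        by_scan.setdefault((det.orientation.value, det.scan_index), []).append(det)
    for orientation in Orientation:
        for k in range(geometry.n_scans_per_orientation):
            lines = []
            for det in by_scan.get((orientation.value, k), []):
                xc = (det.x0 + det.x1) / 2 / geometry.bscan_width
                w = (det.x1 - det.x0) / geometry.bscan_width
                # box height on the B-scan has no en face meaning; a thin
                # centred placeholder keeps the files well-formed
                # 10 decimals keep the sub-pixel extent intact round-trip
                lines.append(
                    f"{erm_class_id} {xc:.10f} 0.5 {w:.10f} 0.1 "
                    f"{det.confidence:.4f}"
                )
            (directory / f"{orientation.value}_{k:02d}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else "")
            )


def write_epi(mask: EPIMask, png_path: str | Path, min_confidence: float | None = None) -> None:
    """8-bit PNG (ERM = 255) plus a JSON sidecar with geometry and provenance."""
    png_path = Path(png_path)
    Image.fromarray((mask.grid.astype(np.uint8)) * 255, mode="L").save(png_path)
    sidecar = {
        "geometry": mask.geometry.to_dict(),
        "erm_pixels": mask.n_true,
        "coverage_max": int(mask.coverage.max()) if mask.coverage.size else 0,
        "coverage_total": int(mask.coverage.sum()),
    }
    if min_confidence is not None:
        sidecar["min_confidence"] = min_confidence
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_epi(png_path: str | Path) -> EPIMask:
    """Read an EPI PNG (+ sidecar geometry if present).

    Per-detection provenance is not recoverable from the flat PNG, so
    coverage is reconstructed as 1 on ERM pixels.
    """
    png_path = Path(png_path)
    arr = np.asarray(Image.open(png_path).convert("L"))
    grid = arr > 127
    sidecar = png_path.with_suffix(".json")
    if sidecar.exists():
        geometry = ScanGeometry.from_dict(json.loads(sidecar.read_text())["geometry"])
    else:
        geometry = ScanGeometry(enface_height=grid.shape[0], enface_width=grid.shape[1])
    return EPIMask(grid=grid, coverage=grid.astype(np.int32), geometry=geometry)


def read_thickness_map(
    path: str | Path, geometry: ScanGeometry | None = None
) -> ThicknessMap:
    """Read a μm thickness grid from CSV or single-channel TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = np.asarray(tifffile.imread(path), dtype=float)
    else:
        grid = np.loadtxt(path, delimiter=",", dtype=float)
    geometry = geometry or ScanGeometry(
        enface_height=grid.shape[0], enface_width=grid.shape[1]
    )
    return ThicknessMap(grid=grid, geometry=geometry)


def write_thickness_map(tmap: ThicknessMap, path: str | Path) -> None:
    path = Path(path)
    grid = np.where(tmap.valid_mask, tmap.grid, np.nan)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, grid.astype(np.float32))
    else:
        np.savetxt(path, grid, delimiter=",", fmt="%.4f")


def read_ratings_csv(path: str | Path, accept_threshold: int = 4) -> ObserverStudy:
    """CSV with a case_id column and one integer column per rater."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.lower() != "case_id"]
    if len(cols) < 2:
        raise ValueError(f"{path}: need a case_id column plus at least 2 rater columns")
    return ObserverStudy(
        ratings=df[cols].to_numpy(dtype=int),
        rater_names=tuple(cols),
        accept_threshold=accept_threshold,
    )


def write_ratings_csv(study: ObserverStudy, path: str | Path) -> None:
    df = pd.DataFrame(study.ratings, columns=list(study.rater_names))
    df.insert(0, "case_id", [f"case_{i + 1:03d}" for i in range(study.n_cases)])
    df.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
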