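"""Star-scan JSON files, result/manifest CSVs, settings provenance.

The scan file format (schema_version "1.0") is a small JSON document, one
per eye:

    {"schema_version": "1.0", "eye": "OD", "axis_deg": 0.0, "n_spokes": 48,
     "spokes": [{"angle_deg": 0.0, "bmo": [x, y, z],
                 "ilm": [[x, y, z], ...]}, ...]}

Coordinates are in mm and may be written in device-native orientation:
left-eye (OS) files are mirrored into the OD frame on load (and mirrored
back on write), so third-party exporters only need to label laterality.
Numbers are serialized with 9 significant digits, which keeps files
diff-able while preserving areas far below the 1e-9 mm^2 round-trip
tolerance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ScanFormatError
from .geometry import ILMCurve, Spoke, StarScan, mirror_scan
from .results import RimAreaResult
from .sectors import GARWAY_HEATH, SectorScheme

__all__ = [
    "read_star_scan",
    "write_star_scan",
    "settings_hash",
    "result_row",
    "write_results_csv",
    "write_manifest_csv",
    "read_sector_scheme",
]

SCHEMA_VERSION = "1.0"
SECTOR_COLUMNS = (
    "nasal",
    "nasal_superior",
    "nasal_inferior",
    "temporal",
    "temporal_superior",
    "temporal_inferior",
)


def _round9(x: float) -> float:
    return float(f"{float(x):.9g}")


def _require(cond: bool, msg: str):
    if not cond:
        raise ScanFormatError(msg)


def read_star_scan(path: str | Path) -> StarScan:
    """Load and validate a scan file; returns a StarScan in the OD frame."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ScanFormatError(f"{path}: not valid JSON ({exc})") from exc
    _require(isinstance(doc, dict), f"{path}: top level must be an object")
    _require(
        doc.get("schema_version") == SCHEMA_VERSION,
        f"{path}: field 'schema_version' must be {SCHEMA_VERSION!r}",
    )
    eye = doc.get("eye")
    _require(eye in ("OD", "OS"), f"{path}: field 'eye' must be 'OD' or 'OS'")
    axis = doc.get("axis_deg", 0.0)
    _require(isinstance(axis, (int, float)), f"{path}: field 'axis_deg' must be a number")
    spokes_doc = doc.get("spokes")
    _require(isinstance(spokes_doc, list) and spokes_doc,
             f"{path}: field 'spokes' must be a non-empty array")
    _require(
        doc.get("n_spokes") == len(spokes_doc),
        f"{path}: field 'n_spokes' ({doc.get('n_spokes')}) does not match "
        f"the {len(spokes_doc)} spokes present",
    )

    spokes = []
    prev_angle = -np.inf
    for k, sd in enumerate(spokes_doc):
        _require(isinstance(sd, dict), f"{path}: spoke {k} must be an object")
        angle = sd.get("angle_deg")
        _require(isinstance(angle, (int, float)) and 0.0 <= angle < 360.0,
                 f"{path}: spoke {k}: field 'angle_deg' must be in [0, 360)")
        _require(angle > prev_angle,
                 f"{path}: spoke {k}: angles must be strictly increasing")
        prev_angle = angle
        bmo = sd.get("bmo")
        _require(
            isinstance(bmo, list) and len(bmo) == 3
            and all(isinstance(v, (int, float)) for v in bmo),
            f"{path}: spoke {k}: field 'bmo' must be [x, y, z]",
        )
        ilm = sd.get("ilm")
        _require(isinstance(ilm, list) and len(ilm) >= 2,
                 f"{path}: spoke {k}: field 'ilm' needs at least 2 points")
        for j, pt in enumerate(ilm):
            _require(
                isinstance(pt, list) and len(pt) == 3
                and all(isinstance(v, (int, float)) for v in pt),
                f"{path}: spoke {k}: ilm point {j} must be [x, y, z]",
            )
        try:
            curve = ILMCurve(np.asarray(ilm, float))
            spokes.append(
                Spoke(index=k, angle_deg=float(angle),
                      bmo_point=np.asarray(bmo, float), ilm_curve=curve)
            )
        except Exception as exc:
            raise ScanFormatError(f"{path}: spoke {k}: {exc}") from exc

    scan = StarScan(eye=eye, spokes=tuple(spokes), axis_deg=float(axis))
    if eye == "OS":
        scan = mirror_scan(scan)  # into OD frame; mirror_scan flips the label
        scan = StarScan(eye="OS", spokes=scan.spokes, axis_deg=scan.axis_deg)
    return scan


def write_star_scan(scan: StarScan, path: str | Path) -> None:
    """Write a scan file; OS scans are mirrored back to device-native
    orientation so write/read round-trips."""
    out = scan
    if scan.eye == "OS":
        out = mirror_scan(StarScan(eye="OD", spokes=scan.spokes, axis_deg=scan.axis_deg))
    doc = {
        "schema_version": SCHEMA_VERSION,
        "eye": scan.eye,
        "axis_deg": _round9(out.axis_deg),
        "n_spokes": out.n_spokes,
        "spokes": [
            {
                "angle_deg": _round9(s.angle_deg),
                "bmo": [_round9(v) for v in s.bmo_point],
                "ilm": [[_round9(v) for v in row] for row in s.ilm_curve.vertices],
            }
            for s in out.spokes
        ],
    }
    Path(path).write_text(json.dumps(doc))


def settings_hash(
    step_mm: float | None, refine: bool, chirality: str, scheme: SectorScheme = GARWAY_HEATH
) -> str:
    """Short provenance hash: changes whenever step, refinement, chirality
    or the sector scheme change."""
    payload = json.dumps(
        {
            "step_mm": step_mm,
            "refine": refine,
            "chirality": chirality,
            "scheme": {"names": scheme.names, "boundaries": scheme.boundaries},
        },
        sort_keys=True,
        default=list,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def result_row(eye_id: str, result: RimAreaResult, bmo_area: float, shash: str) -> dict:
    row = {"eye_id": eye_id, "method": result.method}
    for col in SECTOR_COLUMNS:
        row[col] = result.sector_sums.get(col, 0.0)
    row["global"] = result.total
    row["bmo_area"] = bmo_area
    row["settings_hash"] = shash
    return row


def write_results_csv(rows: list[dict], path: str | Path) -> None:
    cols = ["eye_id", "method", "global", *SECTOR_COLUMNS, "bmo_area", "settings_hash"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def write_manifest_csv(records: list[dict], path: str | Path) -> None:
    cols = ["eye_id", "file", "diagnosis", "md_db", "seed"]
    pd.DataFrame(records)[cols].to_csv(path, index=False)


def read_sector_scheme(path: str | Path) -> SectorScheme:
    """Sector scheme override: {"names": [...], "boundaries": [[lo, hi], ...]}."""
    doc = json.loads(Path(path).read_text())
    _require(isinstance(doc, dict) and "names" in doc and "boundaries" in doc,
             f"{path}: scheme file needs 'names' and 'boundaries'")
    return SectorScheme(
        names=tuple(doc["names"]),
        boundaries=tuple((float(lo), float(hi)) for lo, hi in doc["boundaries"]),
    )
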