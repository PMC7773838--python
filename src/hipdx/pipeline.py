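"""File-level pipeline steps: measure a directory, train a model, classify.

These functions are the importable API behind the command-line interface;
each reads/writes the package's CSV and JSON formats and returns the
in-memory result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import AngleTriplet, measure_pelvis
from .annotations import read_annotation
from .clustering import DensityClustering, density_descending_cluster, select_normal_samples
from .errors import HipdxError, InputError
from .model import (GaussianModel, KnowledgeThresholds, classify_data_driven,
                    classify_knowledge, fit_gaussian, serialize_model)

__all__ = ["measure_annotations", "train_model", "classify_table", "MeasureResult"]

logger = logging.getLogger(__name__)

ANGLE_COLUMNS = ["sample_id", "image_id", "side", "ce_deg", "sharp_deg", "tonnis_deg"]


@dataclass
class MeasureResult:
    table: pd.DataFrame
    n_failed: int
    failures: list[tuple[str, str]]  # (file, error message)


def measure_annotations(path: str | Path, out_csv: str | Path | None = None,
                        neck_present: bool = False) -> MeasureResult:
    """Measure every annotation file under ``path`` (file or directory).

    Produces one row per hip with the three angles rounded to 2 decimals in
    the CSV (full precision in the returned DataFrame).  Files that fail to
    parse or measure are logged and skipped; the count is reported so a
    caller can exit nonzero.
    """
    p = Path(path)
    files = sorted(p.glob("*.json")) if p.is_dir() else [p]
    if not files:
        raise InputError(f"no annotation JSON files found under {p}")
    rows, failures = [], []
    for f in files:
        try:
            ann = read_annotation(f)
            right, left, _ = measure_pelvis(ann, neck_present=neck_present)
        except HipdxError as exc:
            logger.error("skipping %s: %s", f.name, exc)
            failures.append((f.name, str(exc)))
            continue
        for s in (right, left):
            rows.append({"sample_id": s.sample_id, "image_id": ann.image_id,
                         "side": s.side, "ce_deg": s.triplet.ce_deg,
                         "sharp_deg": s.triplet.sharp_deg,
                         "tonnis_deg": s.triplet.tonnis_deg})
    table = pd.DataFrame(rows, columns=ANGLE_COLUMNS)
    if out_csv is not None:
        table.round({"ce_deg": 2, "sharp_deg": 2, "tonnis_deg": 2}).to_csv(
            out_csv, index=False)
    return MeasureResult(table=table, n_failed=len(failures), failures=failures)


def _angles_matrix(table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in ("ce_deg", "sharp_deg", "tonnis_deg") if c not in table]
    if missing:
        raise InputError(f"angle table missing columns: {missing}")
    return table[["ce_deg", "sharp_deg", "tonnis_deg"]].to_numpy(dtype=float)


def train_model(
    angles: pd.DataFrame | str | Path,
    model_out: str | Path | None = None,
    assignments_out: str | Path | None = None,
    bandwidth: float | None = None,
    linking_radius: float | None = None,
    quantile: float = 0.95,
    standardize: bool = False,
) -> tuple[GaussianModel, DensityClustering, np.ndarray]:
    """Cluster an angle table and fit the Gaussian model on the peak cluster.

    Returns ``(model, clustering, normal_indices)``; optionally writes the
    model JSON and a per-sample cluster assignment CSV.
    """
    table = pd.read_csv(angles) if not isinstance(angles, pd.DataFrame) else angles
    x = _angles_matrix(table)
    if len(x) < 4:
        raise InputError(f"need at least 4 samples to train, got {len(x)}")
    clustering = density_descending_cluster(
        x, bandwidth=bandwidth, linking_radius=linking_radius,
        standardize=standardize)
    normal_idx = select_normal_samples(clustering)
    model = fit_gaussian(x[normal_idx], quantile=quantile)
    if model_out is not None:
        serialize_model(model, model_out)
    if assignments_out is not None:
        pd.DataFrame({
            "sample_id": table.get("sample_id", pd.RangeIndex(len(x)).astype(str)),
            "density": clustering.densities,
            "cluster": clustering.labels,
            "is_peak_cluster": clustering.labels == clustering.peak_cluster,
        }).to_csv(assignments_out, index=False)
    return model, clustering, normal_idx


def classify_table(
    model: GaussianModel,
    angles: pd.DataFrame | str | Path,
    thresholds: KnowledgeThresholds | None = None,
    combine_tonnis: bool = False,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Apply both diagnostic criteria to every hip of an angle table.

    Returns one row per (hip, criterion) with label and score.
    """
    table = pd.read_csv(angles) if not isinstance(angles, pd.DataFrame) else angles
    x = _angles_matrix(table)
    ids = table.get("sample_id", pd.RangeIndex(len(x)).astype(str))
    rows = []
    for i in range(len(x)):
        dd = classify_data_driven(model, x[i])
        kd = classify_knowledge(AngleTriplet(*x[i]), thresholds,
                                combine_tonnis=combine_tonnis)
        for d in (dd, kd):
            rows.append({"sample_id": ids[i], "criterion": d.criterion,
                         "label": d.label, "score": d.score})
    out = pd.DataFrame(rows, columns=["sample_id", "criterion", "label", "score"])
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out
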