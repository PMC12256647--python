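"""Radius-corrected nearest-neighbor colocalization and the Colocalization
Index (CI).

The method treats each segmented bouton as a sphere of its equivalent
radius. For every object, the nearest object in the *opposite* channel is
found by exact Euclidean search on centroids; the interbouton distance is
the center distance minus both radii, and two objects are colocalized iff
that distance is strictly negative (i.e. the spheres overlap).

Per image, the percentage of candidate-channel objects colocalized with a
reference object is normalized by the percentage of reference objects
colocalized with a candidate object:

    CI = %candidate colocalized / %reference colocalized

Under the assumption that every reference bouton contains the candidate
marker (e.g. every CTB-filled retinal terminal is VGluT2+), the denominator
absorbs segmentation false positives: CI = 1 means every candidate object
is also reference-labeled, CI < 1 quantifies singly labeled candidates.
CI may exceed 1 through sampling noise.

Group statistics operate on per-image CI values (n = images, not objects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as gstats

__all__ = [
    "ImageColocSummary",
    "nearest_cross_channel",
    "interbouton_distance",
    "percent_colocalized",
    "compute_ci",
    "summarize_image",
    "compare_ci_groups",
]

logger = logging.getLogger(__name__)

COLOC_RECORD_COLUMNS = [
    "object_id",
    "channel",
    "neighbor_id",
    "center_distance_um",
    "interbouton_distance_um",
    "colocalized",
]


@dataclass
class ImageColocSummary:
    """Per-image colocalization outcome."""

    image_id: str
    group: str | None
    n_candidate: int
    n_reference: int
    pct_candidate_coloc: float
    pct_reference_coloc: float
    ci: float
    records: pd.DataFrame | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "group": self.group,
            "n_candidate": self.n_candidate,
            "n_reference": self.n_reference,
            "pct_candidate_coloc": self.pct_candidate_coloc,
            "pct_reference_coloc": self.pct_reference_coloc,
            "ci": self.ci,
        }


def _centroids(table: pd.DataFrame) -> np.ndarray:
    return table[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def nearest_cross_channel(
    candidates: pd.DataFrame, references: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact nearest cross-channel neighbor for every object, both directions.

    Returns ``(candidate_nn, reference_nn)``; each has columns ``object_id,
    neighbor_id, center_distance_um`` where the neighbor is the nearest
    object (Euclidean, on centroids) in the other table. Ties are broken
    toward the lowest neighbor ``object_id``.
    """
    for name, table in (("candidate", candidates), ("reference", references)):
        if len(table) == 0:
            raise ValueError(f"{name} channel has no objects")
    cand = candidates.sort_values("object_id", kind="stable")
    ref = references.sort_values("object_id", kind="stable")
    d = np.linalg.norm(
        _centroids(cand)[:, None, :] - _centroids(ref)[None, :, :], axis=2
    )
    # argmin returns the first minimum; rows/cols are in ascending-id order,
    # so ties resolve to the lowest neighbor id
    cand_nn = pd.DataFrame(
        {
            "object_id": cand["object_id"].to_numpy(),
            "neighbor_id": ref["object_id"].to_numpy()[d.argmin(axis=1)],
            "center_distance_um": d.min(axis=1),
        }
    )
    ref_nn = pd.DataFrame(
        {
            "object_id": ref["object_id"].to_numpy(),
            "neighbor_id": cand["object_id"].to_numpy()[d.argmin(axis=0)],
            "center_distance_um": d.min(axis=0),
        }
    )
    return cand_nn, ref_nn


def interbouton_distance(
    center_distance: float | np.ndarray,
    radius_a: float | np.ndarray,
    radius_b: float | np.ndarray,
) -> float | np.ndarray:
    """Center distance minus both equivalent radii; negative means the two
    spheres overlap (colocalized under the strict < 0 criterion)."""
    center_distance = np.asarray(center_distance, dtype=float)
    radius_a = np.asarray(radius_a, dtype=float)
    radius_b = np.asarray(radius_b, dtype=float)
    if np.any(radius_a < 0) or np.any(radius_b < 0):
        raise ValueError("radii must be non-negative")
    if np.any(center_distance < 0):
        raise ValueError("center distance must be non-negative")
    out = center_distance - radius_a - radius_b
    return float(out) if out.ndim == 0 else out


def percent_colocalized(colocalized: np.ndarray | pd.Series | list) -> float:
    """100 × (number colocalized) / (number of objects)."""
    flags = np.asarray(colocalized, dtype=bool)
    if flags.size == 0:
        raise ValueError("no records: percentage undefined")
    return 100.0 * flags.sum() / flags.size


def compute_ci(pct_candidate_coloc: float, pct_reference_coloc: float) -> float:
    """CI = %candidate colocalized / %reference colocalized."""
    for v in (pct_candidate_coloc, pct_reference_coloc):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percentage out of [0, 100]: {v}")
    if pct_reference_coloc == 0:
        raise ZeroDivisionError(
            "CI undefined: no reference object is colocalized (denominator 0)"
        )
    return pct_candidate_coloc / pct_reference_coloc


def _records_for(
    table: pd.DataFrame, nn: pd.DataFrame, other: pd.DataFrame, channel: str
) -> pd.DataFrame:
    t = table.sort_values("object_id", kind="stable")
    radius_self = t.set_index("object_id")["radius_um"]
    radius_other = other.set_index("object_id")["radius_um"]
    dist = interbouton_distance(
        nn["center_distance_um"].to_numpy(),
        radius_self.loc[nn["object_id"]].to_numpy(),
        radius_other.loc[nn["neighbor_id"]].to_numpy(),
    )
    return pd.DataFrame(
        {
            "object_id": nn["object_id"].to_numpy(),
            "channel": channel,
            "neighbor_id": nn["neighbor_id"].to_numpy(),
            "center_distance_um": nn["center_distance_um"].to_numpy(),
            "interbouton_distance_um": dist,
            "colocalized": dist < 0,  # strictly negative: 0 is NOT colocalized
        },
        columns=COLOC_RECORD_COLUMNS,
    )


def summarize_image(
    candidates: pd.DataFrame,
    references: pd.DataFrame,
    *,
    image_id: str = "image",
    group: str | None = None,
    min_objects_warn: int = 200,
) -> ImageColocSummary:
    """Full per-image colocalization: nearest neighbors both ways,
    interbouton distances, colocalization percentages and CI.

    Logs a warning (not an error) when either channel has fewer than
    ``min_objects_warn`` objects — images in this analysis are expected to
    carry at least ~200 boutons per channel for stable percentages.
    """
    for name, table in (("candidate", candidates), ("reference", references)):
        if len(table) < min_objects_warn:
            logger.warning(
                "image %s: %s channel has %d objects (< %d); "
                "percentages may be unstable",
                image_id,
                name,
                len(table),
                min_objects_warn,
            )
    cand_nn, ref_nn = nearest_cross_channel(candidates, references)
    cand_records = _records_for(candidates, cand_nn, references, "candidate")
    ref_records = _records_for(references, ref_nn, candidates, "reference")
    pct_c = percent_colocalized(cand_records["colocalized"])
    pct_r = percent_colocalized(ref_records["colocalized"])
    return ImageColocSummary(
        image_id=image_id,
        group=group,
        n_candidate=len(candidates),
        n_reference=len(references),
        pct_candidate_coloc=pct_c,
        pct_reference_coloc=pct_r,
        ci=compute_ci(pct_c, pct_r),
        records=pd.concat([cand_records, ref_records], ignore_index=True),
    )


def compare_ci_groups(
    summaries: list[ImageColocSummary],
    grouping: dict[str, str] | None = None,
) -> dict:
    """Group per-image CI values and compare the two groups with Welch's t.

    ``grouping`` maps image group labels to comparison groups; when omitted,
    each summary's own ``group`` is used. Requires exactly two groups with at
    least two images each. Returns per-group descriptives (n, mean, SEM, 95%
    CI) and the Welch test result.
    """
    values: dict[str, list[float]] = {}
    for s in summaries:
        label = s.group if s.group is not None else "all"
        key = grouping.get(label, label) if grouping else label
        values.setdefault(key, []).append(s.ci)
    for key, v in values.items():
        if len(v) < 2:
            raise ValueError(f"group {key!r} has {len(v)} image(s); need >= 2")
    if len(values) != 2:
        raise ValueError(f"Welch comparison needs exactly 2 groups, got {len(values)}")
    (g1, x), (g2, y) = sorted(values.items())
    welch = gstats.two_sample_test(x, y, method="welch")
    return {
        "groups": {
            g: gstats.describe_group(v)._asdict() for g, v in sorted(values.items())
        },
        "test": welch.to_dict(),
        "comparison": f"{g1} vs {g2}",
    }
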