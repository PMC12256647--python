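"""Synthetic ground-truth scenes and soma-size samples.

Every downstream stage of the pipeline (segmentation, colocalization,
mixture modeling) is exercised against data produced here, so the scene
generator records full ground truth: object centers, radii and the
reference<->candidate pairings that define true colocalization.

Conventions
-----------
* Physical coordinates are (x, y, z) in micrometers; voxel arrays are
  indexed (z, y, x) with the physical center of voxel ``i`` at
  ``(i + 0.5) * spacing``.
* Channel roles are ``"reference"`` (tracer-filled, e.g. CTB) and
  ``"candidate"`` (immunolabel, e.g. VGluT2); the colocalization index is
  directional, candidate over reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VoxelGrid

__all__ = [
    "SceneObject",
    "GroundTruthScene",
    "generate_coloc_scene",
    "render_scene",
    "sample_soma_sizes",
    "PlacementError",
]

REFERENCE = "reference"
CANDIDATE = "candidate"

#: hard cap on rendered grid size, guards runaway allocation
MAX_RENDER_VOXELS = 300_000_000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an object."""


@dataclass(frozen=True)
class SceneObject:
    """One spherical bouton in a ground-truth scene."""

    object_id: int
    channel: str  # "reference" | "candidate"
    x: float
    y: float
    z: float
    radius: float
    paired_id: int | None = None  # id of the partner object in the other channel

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class GroundTruthScene:
    """A field of paired and unpaired boutons with known colocalization.

    ``bbox`` is the physical extent (size_x, size_y, size_z) in μm. Every
    reference object carries exactly one overlapping candidate partner;
    extra candidate objects are unpaired, so the true candidate-channel
    colocalization fraction is ``n_reference / n_candidate``.
    """

    bbox: tuple[float, float, float]
    objects: list[SceneObject] = field(default_factory=list)
    requested_fraction: float = 1.0

    def channel_objects(self, channel: str) -> list[SceneObject]:
        return [o for o in self.objects if o.channel == channel]

    @property
    def n_reference(self) -> int:
        return len(self.channel_objects(REFERENCE))

    @property
    def n_candidate(self) -> int:
        return len(self.channel_objects(CANDIDATE))

    @property
    def true_candidate_fraction(self) -> float:
        """Fraction of candidate objects that have a reference partner."""
        cand = self.channel_objects(CANDIDATE)
        if not cand:
            return float("nan")
        paired = sum(1 for o in cand if o.paired_id is not None)
        return paired / len(cand)

    def to_frame(self) -> pd.DataFrame:
        """One row per object: channel, x, y, z, radius, paired_id."""
        return pd.DataFrame(
            {
                "object_id": [o.object_id for o in self.objects],
                "channel": [o.channel for o in self.objects],
                "x": [o.x for o in self.objects],
                "y": [o.y for o in self.objects],
                "z": [o.z for o in self.objects],
                "radius": [o.radius for o in self.objects],
                "paired_id": [
                    -1 if o.paired_id is None else o.paired_id for o in self.objects
                ],
            }
        )

    def to_object_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Ground-truth (candidate, reference) object tables in the
        segmentation table schema, with exact centers and radii.

        Lets downstream colocalization run directly on the truth, bypassing
        rendering; ``voxel_count`` is 0 (nothing was rasterized) and volume
        is the analytic sphere volume.
        """
        def table(channel: str) -> pd.DataFrame:
            objs = self.channel_objects(channel)
            radius = np.array([o.radius for o in objs])
            return pd.DataFrame(
                {
                    "object_id": [o.object_id for o in objs],
                    "channel": channel,
                    "voxel_count": 0,
                    "volume_um3": 4.0 / 3.0 * np.pi * radius**3,
                    "x_um": [o.x for o in objs],
                    "y_um": [o.y for o in objs],
                    "z_um": [o.z for o in objs],
                    "radius_um": radius,
                }
            )

        return table(CANDIDATE), table(REFERENCE)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, bbox: tuple[float, float, float]) -> "GroundTruthScene":
        objs = [
            SceneObject(
                object_id=int(r.object_id),
                channel=str(r.channel),
                x=float(r.x),
                y=float(r.y),
                z=float(r.z),
                radius=float(r.radius),
                paired_id=None if int(r.paired_id) < 0 else int(r.paired_id),
            )
            for r in frame.itertuples()
        ]
        n_cand = sum(1 for o in objs if o.channel == CANDIDATE)
        n_ref = sum(1 for o in objs if o.channel == REFERENCE)
        frac = n_ref / n_cand if n_cand else 1.0
        return cls(bbox=bbox, objects=objs, requested_fraction=frac)


def _sample_center(
    rng: np.random.Generator, bbox: tuple[float, float, float], margin: float
) -> np.ndarray | None:
    lo = margin
    hi = np.asarray(bbox, dtype=float) - margin
    if np.any(hi <= lo):
        return None
    return rng.uniform(lo, hi)


def _clear_of(
    center: np.ndarray,
    radius: float,
    placed: list[tuple[np.ndarray, float]],
    min_separation: float,
) -> bool:
    for c, r in placed:
        if np.linalg.norm(center - c) < radius + r + min_separation:
            return False
    return True


def generate_coloc_scene(
    n_reference: int,
    n_extra_candidate: int,
    *,
    radius_median: float = 0.5,
    radius_sigma: float = 0.3,
    pair_offset_max: float = 0.3,
    bbox: tuple[float, float, float] = (36.0, 36.0, 12.0),
    min_separation: float = 0.5,
    seed: int,
    max_tries: int = 10_000,
) -> GroundTruthScene:
    """Place ``n_reference`` overlapping reference/candidate pairs plus
    ``n_extra_candidate`` unpaired candidate objects.

    Radii are lognormal with the given median (μm) and log-sd; each paired
    candidate center is offset from its reference by a uniform random vector
    of length at most ``min(pair_offset_max, 0.5 * min(r_ref, r_cand))``,
    which guarantees the pair overlaps (center distance < sum of radii).
    All *other* object pairs keep a surface-to-surface distance of at least
    ``min_separation``, so unpaired candidates never overlap a reference.

    Rejection sampling; raises :class:`PlacementError` after ``max_tries``
    failed placements for any single object.
    """
    if n_reference < 0 or n_extra_candidate < 0:
        raise ValueError("object counts must be non-negative")
    if min_separation < 0:
        raise ValueError("min_separation must be non-negative")
    rng = np.random.default_rng(seed)
    mu = math.log(radius_median)

    objects: list[SceneObject] = []
    placed: list[tuple[np.ndarray, float]] = []  # collision set
    next_id = 0

    def draw_radius() -> float:
        return float(rng.lognormal(mean=mu, sigma=radius_sigma))

    for _ in range(n_reference):
        for attempt in range(max_tries):
            r_ref = draw_radius()
            r_cand = draw_radius()
            cap = min(pair_offset_max, 0.5 * min(r_ref, r_cand))
            margin = max(r_ref, r_cand + cap)
            center = _sample_center(rng, bbox, margin)
            if center is None:
                raise PlacementError(
                    f"bbox {bbox} too small for an object of radius {margin:.2f} μm"
                )
            # random offset direction, length uniform in [0, cap]
            direction = rng.normal(size=3)
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            offset = direction * rng.uniform(0.0, cap)
            cand_center = center + offset
            if _clear_of(center, r_ref, placed, min_separation) and _clear_of(
                cand_center, r_cand, placed, min_separation
            ):
                break
        else:
            raise PlacementError(
                f"could not place reference pair after {max_tries} tries "
                f"(bbox {bbox}, min_separation {min_separation})"
            )
        ref = SceneObject(next_id, REFERENCE, *center, radius=r_ref, paired_id=next_id + 1)
        cand = SceneObject(
            next_id + 1, CANDIDATE, *cand_center, radius=r_cand, paired_id=next_id
        )
        next_id += 2
        objects += [ref, cand]
        placed += [(center, r_ref), (cand_center, r_cand)]

    for _ in range(n_extra_candidate):
        for attempt in range(max_tries):
            r = draw_radius()
            center = _sample_center(rng, bbox, r)
            if center is None:
                raise PlacementError(
                    f"bbox {bbox} too small for an object of radius {r:.2f} μm"
                )
            if _clear_of(center, r, placed, min_separation):
                break
        else:
            raise PlacementError(
                f"could not place unpaired candidate after {max_tries} tries"
            )
        objects.append(SceneObject(next_id, CANDIDATE, *center, radius=r, paired_id=None))
        next_id += 1
        placed.append((center, r))

    n_cand = n_reference + n_extra_candidate
    frac = n_reference / n_cand if n_cand else 1.0
    return GroundTruthScene(bbox=tuple(bbox), objects=objects, requested_fraction=frac)


def render_scene(
    scene: GroundTruthScene,
    *,
    voxel_spacing: tuple[float, float, float] = (0.3, 0.06, 0.06),
    psf_sigma: float = 0.1,
    amplitude: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_voxels: int = MAX_RENDER_VOXELS,
) -> VoxelGrid:
    """Render a scene into a two-channel voxel grid.

    Each object is painted as a solid sphere of its physical radius (a voxel
    belongs to the sphere iff its center lies inside), then each channel is
    blurred with an anisotropy-aware Gaussian of physical sigma ``psf_sigma``
    and additive Gaussian noise (sd ``noise_sd``) is applied per voxel and
    clipped at zero. Channels are rendered independently.

    ``voxel_spacing`` is (z, y, x) in μm.
    """
    from scipy.ndimage import gaussian_filter

    spacing = np.asarray(voxel_spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be strictly positive")
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be non-negative")
    ex, ey, ez = scene.bbox
    shape = (
        max(1, math.ceil(ez / spacing[0])),
        max(1, math.ceil(ey / spacing[1])),
        max(1, math.ceil(ex / spacing[2])),
    )
    n_vox = 2 * int(np.prod(shape))
    if n_vox > max_voxels:
        raise ValueError(
            f"render of {n_vox} voxels exceeds max_voxels={max_voxels}; "
            "coarsen voxel_spacing or shrink the scene"
        )

    data = np.zeros((2, *shape), dtype=np.float32)
    channel_index = {REFERENCE: 0, CANDIDATE: 1}
    for obj in scene.objects:
        _paint_sphere(
            data[channel_index[obj.channel]],
            spacing,
            center_zyx=np.array([obj.z, obj.y, obj.x]),
            radius=obj.radius,
            value=amplitude,
        )

    if psf_sigma > 0:
        sigma_vox = psf_sigma / spacing
        for c in range(2):
            data[c] = gaussian_filter(data[c], sigma=sigma_vox)
    data += background
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
        np.clip(data, 0.0, None, out=data)
    return VoxelGrid(data=data, spacing=tuple(spacing), channels=(REFERENCE, CANDIDATE))


def _paint_sphere(
    volume: np.ndarray,
    spacing: np.ndarray,
    center_zyx: np.ndarray,
    radius: float,
    value: float,
) -> None:
    """Set voxels whose centers lie within ``radius`` of the center (max with
    current value, so overlapping same-channel objects don't double)."""
    lo = np.maximum(np.floor((center_zyx - radius) / spacing - 0.5).astype(int), 0)
    hi = np.minimum(
        np.ceil((center_zyx + radius) / spacing - 0.5).astype(int) + 1,
        np.asarray(volume.shape),
    )
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) + 0.5) * spacing[0],
        (np.arange(lo[1], hi[1]) + 0.5) * spacing[1],
        (np.arange(lo[2], hi[2]) + 0.5) * spacing[2],
        indexing="ij",
    )
    inside = (
        (zz - center_zyx[0]) ** 2 + (yy - center_zyx[1]) ** 2 + (xx - center_zyx[2]) ** 2
    ) <= radius**2
    sub = volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[inside] = np.maximum(sub[inside], value)


def sample_soma_sizes(
    components: list[tuple[float, float, float]],
    n: int,
    *,
    seed: int,
    lamina: str = "L1",
    gaba_status: str = "-",
) -> pd.DataFrame:
    """Draw ``n`` soma areas (μm²) from a mixture of normal components.

    ``components`` is a list of (weight, mean, sd). Returns a DataFrame with
    columns ``area_um2``, ``lamina``, ``gaba_status`` and the ground-truth
    ``component`` label (index into ``components``, sorted as given).
    Non-positive draws are rejected and redrawn, keeping areas > 0.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    comps = [(float(w), float(m), float(s)) for w, m, s in components]
    weights = np.array([c[0] for c in comps])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"component weights must sum to 1, got {weights.sum()!r}")
    if any(c[2] <= 0 for c in comps):
        raise ValueError("component sds must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(comps), size=n, p=weights)
    areas = np.empty(n)
    for i, k in enumerate(labels):
        _, m, s = comps[k]
        a = rng.normal(m, s)
        while a <= 0:  # truncate at zero: soma areas are positive
            a = rng.normal(m, s)
        areas[i] = a
    return pd.DataFrame(
        {
            "area_um2": areas,
            "lamina": lamina,
            "gaba_status": gaba_status,
            "component": labels.astype(int),
        }
    )
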