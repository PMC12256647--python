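"""Reference analyses on synthetic scenes with known ground truth.

These functions define the package's canonical self-checks: the CI of a
fully paired scene (identity case), the CI of a scene with a known fraction
of singly labeled candidates (deficit case), and the end-to-end recovery
sweep. They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

from . import coloc, synthetic
from .segmentation import segment_channel

#: rendering/segmentation settings for the benchmark scenes: the study's
#: axial step with a 2x-coarsened lateral step, noiseless, fixed mid-range
#: threshold (amplitude 100 over background 10)
BENCH_SPACING = (0.3, 0.12, 0.12)
BENCH_THRESHOLD = 55.0


def ci_identity_from_truth(n_reference: int = 100, seed: int = 1) -> coloc.ImageColocSummary:
    """CI of a fully paired scene, computed on ground-truth centers/radii.

    Every candidate overlaps its reference and vice versa, so both
    colocalization percentages are 100 and CI is exactly 1.
    """
    scene = synthetic.generate_coloc_scene(n_reference, 0, seed=seed)
    cand, ref = scene.to_object_tables()
    return coloc.summarize_image(cand, ref, image_id="identity", min_objects_warn=0)


def ci_from_rendered_scene(
    n_reference: int,
    n_extra_candidate: int,
    seed: int,
    *,
    psf_sigma: float = 0.1,
    noise_sd: float = 0.0,
    sigma_um: float = 0.0,
    min_voxels: int = 15,
) -> tuple[coloc.ImageColocSummary, synthetic.GroundTruthScene]:
    """Full pipeline on one scene: generate, render noiselessly, segment
    both channels with a fixed mid-range threshold, summarize."""
    scene = synthetic.generate_coloc_scene(n_reference, n_extra_candidate, seed=seed)
    grid = synthetic.render_scene(
        scene,
        voxel_spacing=BENCH_SPACING,
        psf_sigma=psf_sigma,
        noise_sd=noise_sd,
        seed=seed,
    )
    tables = {
        ch: segment_channel(
            grid, ch, sigma_um=sigma_um, threshold=BENCH_THRESHOLD, min_voxels=min_voxels
        )
        for ch in ("candidate", "reference")
    }
    summary = coloc.summarize_image(
        tables["candidate"],
        tables["reference"],
        image_id=f"scene_seed{seed}",
        min_objects_warn=0,
    )
    return summary, scene


def recovery_sweep(
    fractions=(1.0, 0.8, 0.5, 0.2),
    seeds=range(1, 21),
    n_candidate_total: int = 150,
) -> list[dict]:
    """Pipeline CI vs ground-truth pairing fraction over a seed sweep.

    Each scene holds ``n_candidate_total`` candidate objects of which
    ``fraction`` are paired, so the ground-truth CI equals the fraction.
    Returns one record per (fraction, seed) with the measured CI.
    """
    out = []
    for frac in fractions:
        n_ref = round(frac * n_candidate_total)
        n_extra = n_candidate_total - n_ref
        for seed in seeds:
            summary, scene = ci_from_rendered_scene(n_ref, n_extra, seed, psf_sigma=0.0)
            out.append(
                {
                    "fraction": frac,
                    "seed": seed,
                    "ci": summary.ci,
                    "truth": scene.true_candidate_fraction,
                    "error": summary.ci - scene.true_candidate_fraction,
                }
            )
    return out
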