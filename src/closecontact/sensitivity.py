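"""Detection-sensitivity characterization of the close-contact pipeline.

Sub-diffraction contacts survive PSF blur only as shallow dips in the
glycocalyx channel, so their detectability depends jointly on diameter and
exclusion depth.  This module measures, by simulation, the exclusion depth
above which the default segmentation reliably picks up a contact of a given
diameter — the same sweep used to establish that contacts below the
diffraction limit are detectable once their exclusion exceeds ~40%.
"""

from __future__ import annotations

import numpy as np

from .render import apply_camera_noise, make_ground_truth_frame, render_frame
from .scene import CameraModel, ContactTruth, GroundTruthScene, PSFModel
from .segmentation import SegmentationConfig, segment_close_contacts
from .video import ImageVideo


def _truth_mask(scene: GroundTruthScene, shape, pixel_um: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, bool)
    for c in scene.contacts:
        cy = c.center_um[0] / pixel_um - 0.5
        cx = c.center_um[1] / pixel_um - 0.5
        r = max(c.diameter_um / 2 / pixel_um, 1.0)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def contact_detected(
    scene: GroundTruthScene,
    seed: int,
    n_frames: int = 10,
    psf: PSFModel | None = None,
    camera: CameraModel | None = None,
    config: SegmentationConfig | None = None,
    supersample: int = 20,
    min_frame_fraction: float = 0.5,
) -> bool:
    """Render one noisy realization of a static scene and report whether the
    default segmentation finds the contact in a majority of frames."""
    psf = psf or PSFModel()
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    res_nm = camera.pixel_size_nm / supersample
    truth = make_ground_truth_frame(scene, 0.0, res_nm, camera)
    ideal = render_frame(truth, psf, camera, res_nm) * camera.quantum_efficiency
    frames = np.stack([apply_camera_noise(ideal, camera, rng) for _ in range(n_frames)])
    pixel_um = camera.pixel_size_nm / 1000.0
    video = ImageVideo(frames, pixel_um, scene.frame_interval_s, "glycocalyx")
    labels = segment_close_contacts(video, None, config, restrict_to_cells=False)
    tmask = _truth_mask(scene, frames.shape[1:], pixel_um)
    hits = sum(1 for f in range(n_frames) if (labels.labels[f][tmask] > 0).any())
    return hits / n_frames > min_frame_fraction


def detectability_threshold(
    diameter_um: float = 0.25,
    exclusion_levels: np.ndarray | None = None,
    n_realizations: int = 20,
    seed: int = 0,
    field_um: float = 3.0,
    n_frames: int = 10,
    config: SegmentationConfig | None = None,
) -> dict:
    """Sweep exclusion depths and return the lowest at which a majority of
    noise realizations detect a contact of the given diameter.

    Returns a dict with the threshold (as a percentage, NaN if no level is
    detectable), the per-level detection fractions, and the total number of
    realizations simulated.
    """
    if exclusion_levels is None:
        exclusion_levels = np.arange(0.1, 1.01, 0.1)
    rng = np.random.default_rng(seed)
    center = (field_um / 2, field_um / 2)
    fractions = []
    for depth in exclusion_levels:
        scene = GroundTruthScene(
            field_size_um=(field_um, field_um),
            contacts=[ContactTruth(center, diameter_um, float(depth))],
            n_frames=n_frames,
        )
        seeds = rng.integers(0, 2**31 - 1, size=n_realizations)
        hits = sum(
            contact_detected(scene, int(s), n_frames=n_frames, config=config)
            for s in seeds
        )
        fractions.append(hits / n_realizations)
    fractions = np.asarray(fractions)
    detectable = fractions > 0.5
    threshold = float(exclusion_levels[np.argmax(detectable)] * 100) if detectable.any() else float("nan")
    return {
        "threshold_percent": threshold,
        "exclusion_levels": np.asarray(exclusion_levels),
        "detection_fraction": fractions,
        "n_realizations_total": int(n_realizations * len(exclusion_levels)),
    }
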