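"""Segmentation of cell footprints and close contacts in TIRFM time-lapses.

Close contacts are the micron-scale dark holes a T cell punches into the
fluorescent glycocalyx layer on the bilayer.  They are detected on the
flat-field-corrected glycocalyx channel with a band-pass (LoG) filter and a
hysteresis threshold whose bounds are set in units of the noise standard
deviation measured outside segmented cell areas ("notCZ" pixels).  Large,
late contacts that the edge-sensitive LoG under-segments are recovered with
a second, intensity-based threshold on an edge-enhanced image.  Cell
footprints are segmented on the membrane channel (DoG + dual threshold) and
labeled with a watershed run over (time, y, x) so a cell keeps one label
throughout the video.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import apply_hysteresis_threshold, threshold_otsu
from skimage.morphology import disk, erosion
from skimage.segmentation import watershed

from .video import ImageVideo


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline.

    Hysteresis bounds ``h_low``/``h_high`` and the late-contact threshold
    ``h2`` are multiples of the notCZ standard deviation; they are
    deliberately user-set (contact size and contrast vary between bilayer
    compositions) and the defaults here were chosen on simulated videos.
    """

    h_low: float = 3.0
    h_high: float = 5.0
    h2: float = 2.0
    dog_sigma_small_px: float = 1.0
    dog_sigma_large_px: float | None = None  # default: cell radius / 2 in px
    cell_radius_um: float = 5.0
    min_cell_area_um2: float = 20.0
    min_contact_area_px: int = 2
    min_persistence_frames: int = 5
    rolling_ball_radius_t: int = 5
    gauss_sigma_xy_px: float = 1.0
    membrane_global_threshold: float | None = None  # default: 4 robust SD above median
    max_otsu_foreground_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.h_low >= self.h_high:
            raise ValueError("h_low must be below h_high")
        if self.gauss_sigma_xy_px <= 0 or self.dog_sigma_small_px <= 0:
            raise ValueError("filter sigmas must be positive")
        if self.min_contact_area_px < 1:
            raise ValueError("min_contact_area must be at least one pixel")

    def dog_large(self, pixel_size_um: float) -> float:
        if self.dog_sigma_large_px is not None:
            return self.dog_sigma_large_px
        return 0.5 * self.cell_radius_um / pixel_size_um


@dataclass
class LabelVolume:
    """Integer labels over (time, y, x); 0 is background."""

    labels: np.ndarray
    kind: str  # "cell" | "close_contact"
    pixel_size_um: float
    frame_interval_s: float
    contact_to_cell: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be (time, y, x)")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


def minimum_reportable_area_um2(pixel_size_um: float = 0.107) -> float:
    """Smallest reportable contact area: segmentation is pixel-based, so one
    camera pixel (0.011 um^2 at 107 nm) is the floor."""
    return pixel_size_um**2


def flatfield_correct(video: ImageVideo, flatfield_stack: np.ndarray) -> ImageVideo:
    """Divide by the flat-field obtained by time-summing a cell-free stack
    and normalizing it to mean 1."""
    ff = np.asarray(flatfield_stack, float)
    if ff.ndim == 3:
        ff = ff.sum(axis=0)
    if np.any(ff <= 0):
        raise ValueError("flat-field contains non-positive pixels")
    ff = ff / ff.mean()
    return video.with_data(video.data / ff)


def correct_membrane_background(
    video: ImageVideo, dim_fraction: float = 0.2
) -> ImageVideo:
    """Remove the linearly increasing background of the membrane channel.

    The membrane dye progressively stains the bilayer itself, raising the
    whole frame over time.  The background level per frame is estimated from
    the dimmest ``dim_fraction`` of pixels (approximately cell-free bilayer),
    fitted linearly against time, and the fitted rise above the first frame
    is subtracted; cell contrast is untouched.
    """
    if video.n_frames < 3:
        raise ValueError("background fit needs at least 3 frames")
    data = np.asarray(video.data, float)
    levels = []
    for f in data:
        q = np.quantile(f, dim_fraction)
        levels.append(f[f <= q].mean())
    t = np.arange(video.n_frames, dtype=float)
    slope, intercept = np.polyfit(t, np.asarray(levels), 1)
    trend = slope * t  # keep the frame-0 level, remove only the rise
    return video.with_data(data - trend[:, None, None])


def _dog(frame: np.ndarray, s_small: float, s_large: float) -> np.ndarray:
    return ndimage.gaussian_filter(frame, s_small) - ndimage.gaussian_filter(frame, s_large)


def segment_membrane(video: ImageVideo, config: SegmentationConfig | None = None) -> np.ndarray:
    """Binary cell-footprint mask per frame.

    Each frame is DoG-filtered, then thresholded with the union of a global
    custom threshold and a per-frame Otsu threshold; the Otsu contribution is
    discarded when it would select an implausibly large foreground fraction
    (pure-noise frames lack the bimodality Otsu assumes).  Components below
    ``min_cell_area_um2`` are removed.
    """
    config = config or SegmentationConfig()
    px = video.pixel_size_um
    s_large = config.dog_large(px)
    min_area_px = int(round(config.min_cell_area_um2 / px**2))

    masks = np.zeros(video.shape, bool)
    for i, frame in enumerate(np.asarray(video.data, float)):
        dog = _dog(frame, config.dog_sigma_small_px, s_large)
        if config.membrane_global_threshold is not None:
            global_thr = config.membrane_global_threshold
        else:
            # robust noise scale: the full SD is inflated by the cells themselves
            med = np.median(dog)
            sigma = 1.4826 * np.median(np.abs(dog - med))
            global_thr = med + 4.0 * sigma
        mask = dog > global_thr
        try:
            otsu = threshold_otsu(dog)
            otsu_mask = dog > otsu
            if otsu_mask.mean() <= config.max_otsu_foreground_fraction:
                mask |= otsu_mask
        except ValueError:
            pass  # constant frame
        # the DoG responds at the footprint edge and texture; fill the interior
        mask = ndimage.binary_fill_holes(mask)
        # min-area filter
        lab, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(lab.ravel())
            keep = sizes >= min_area_px
            keep[0] = False
            mask = keep[lab]
        masks[i] = mask
    return masks


def label_cells(
    mask_volume: np.ndarray,
    config: SegmentationConfig | None = None,
    pixel_size_um: float = 0.107,
    frame_interval_s: float = 2.0,
    seed_overrides: np.ndarray | None = None,
    intensity_video: ImageVideo | None = None,
) -> LabelVolume:
    """Assign one label per cell across the whole video with a 3-D watershed.

    Seeds are local maxima (separated by at least the cell radius) on the
    last frame — adhered cells barely move, so their masks overlap in time
    and the watershed floods each cell's whole spatiotemporal mask from a
    single seed.  Seeds come from the larger-DoG-filtered last intensity
    frame when the intensity video is supplied, otherwise from the distance
    transform of the last mask frame.  ``seed_overrides`` rows (t, y, x,
    label) replace the automatic seeds (file-based stand-in for manual seed
    editing).  Disconnected mask components are attached to the nearest
    label within twice the cell radius in (x, y, t), searching backward in
    time; unattachable components are dropped.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(mask_volume, bool)
    if not mask.any():
        raise ValueError("mask volume is empty; nothing to label")
    radius_px = max(1, int(round(config.cell_radius_um / pixel_size_um)))

    markers = np.zeros(mask.shape, np.int32)
    if seed_overrides is not None and len(seed_overrides):
        for row in np.atleast_2d(np.asarray(seed_overrides, int)):
            t, y, x, lab = row
            markers[t, y, x] = lab
    else:
        last = mask.shape[0] - 1
        if intensity_video is not None:
            surface = _dog(np.asarray(intensity_video.data[last], float),
                           config.dog_sigma_small_px, config.dog_large(pixel_size_um))
        else:
            surface = ndimage.distance_transform_edt(mask[last])
        peaks = peak_local_max(
            surface, min_distance=radius_px, labels=mask[last], exclude_border=False
        )
        if len(peaks) == 0:
            raise ValueError(f"no watershed seeds found on frame {last}")
        for lab, (y, x) in enumerate(peaks, start=1):
            markers[last, y, x] = lab
    if not markers.any():
        raise ValueError("no seeds available (empty overrides)")

    # snap seeds onto the mask so the watershed can flood from them
    seed_pos = np.argwhere(markers > 0)
    mask_pos = np.argwhere(mask)
    tree = cKDTree(mask_pos)
    snapped = np.zeros_like(markers)
    for t, y, x in seed_pos:
        lab = markers[t, y, x]
        if mask[t, y, x]:
            snapped[t, y, x] = lab
        else:
            _, idx = tree.query([t, y, x])
            snapped[tuple(mask_pos[idx])] = lab

    edt = ndimage.distance_transform_edt(mask)
    labels = watershed(-edt, snapped, mask=mask)

    # attach orphan components (mask voxels the watershed could not reach)
    orphan = mask & (labels == 0)
    if orphan.any():
        labeled_pos = np.argwhere(labels > 0)
        ltree = cKDTree(labeled_pos)
        comp, n = ndimage.label(orphan, structure=np.ones((3, 3, 3), bool))
        for c in range(1, n + 1):
            voxels = np.argwhere(comp == c)
            first_t = voxels[:, 0].min()
            # nearest labeled voxel, searching backward in time
            dists, idxs = ltree.query(voxels, k=1)
            order = np.argsort(dists)
            assigned = 0
            for o in order:
                cand = labeled_pos[idxs[o]]
                if cand[0] <= first_t and dists[o] <= 2 * radius_px:
                    assigned = labels[tuple(cand)]
                    break
            if assigned == 0:
                # fall back to any direction within range
                if dists[order[0]] <= 2 * radius_px:
                    assigned = labels[tuple(labeled_pos[idxs[order[0]]])]
            if assigned:
                labels[comp == c] = assigned
    return LabelVolume(labels.astype(np.int32), "cell", pixel_size_um, frame_interval_s)


def _temporal_rolling_mean(data: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or data.shape[0] == 1:
        return data
    window = min(window, data.shape[0])
    return ndimage.uniform_filter1d(data, size=window, axis=0, mode="nearest")


def segment_close_contacts(
    glyco_video: ImageVideo,
    cell_labels: LabelVolume | None,
    config: SegmentationConfig | None = None,
    restrict_to_cells: bool = True,
) -> LabelVolume:
    """Detect and label close contacts on the glycocalyx channel.

    The flat-field-corrected stack is smoothed with a temporal running mean
    (``rolling_ball_radius_t`` frames) and a spatial Gaussian, and its
    Laplacian taken (LoG overall; dark holes give positive LoG).  Per frame,
    contacts are the union of (i) a hysteresis threshold on the LoG at
    ``h_low``/``h_high`` notCZ standard deviations and (ii) an eroded
    late-contact mask where the edge-enhanced image (Gaussian + LoG) falls
    below ``mean - h2 * std`` of the notCZ Gaussian image.  Components
    smaller than ``min_contact_area_px`` are removed; surviving detections
    are labeled in 3-D (temporal overlap connects frames) and mapped to the
    owning cell.
    """
    config = config or SegmentationConfig()
    data = np.asarray(glyco_video.data, float)
    if cell_labels is None and restrict_to_cells:
        import warnings

        warnings.warn("no cell labels supplied; close contacts are unrestricted")
        restrict_to_cells = False

    smoothed = _temporal_rolling_mean(data, config.rolling_ball_radius_t)
    gauss = np.stack(
        [ndimage.gaussian_filter(f, config.gauss_sigma_xy_px) for f in smoothed]
    )
    # Laplacian of the Gaussian-smoothed stack; a dark hole is a local
    # minimum, where the Laplacian is positive
    log = np.stack([ndimage.laplace(f) for f in gauss])

    detected = np.zeros(data.shape, bool)
    for f in range(data.shape[0]):
        if cell_labels is not None:
            not_cz = cell_labels.labels[f] == 0
            if not not_cz.any():
                not_cz = np.ones(data.shape[1:], bool)
        else:
            not_cz = np.ones(data.shape[1:], bool)
        std_log = log[f][not_cz].std()
        if std_log == 0:
            continue
        mask = apply_hysteresis_threshold(
            log[f], config.h_low * std_log, config.h_high * std_log
        )
        g_not = gauss[f][not_cz]
        late_thr = g_not.mean() - config.h2 * g_not.std()
        late = erosion((gauss[f] - log[f]) < late_thr, disk(1))
        mask |= late
        if restrict_to_cells and cell_labels is not None:
            mask &= cell_labels.labels[f] > 0
        # minimum-size filter (pixel-based; 1 px = the resolution floor)
        lab, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(lab.ravel())
            keep = sizes >= config.min_contact_area_px
            keep[0] = False
            mask = keep[lab]
        detected[f] = mask

    # 3-D labeling: 8-connectivity in-plane, plus direct temporal overlap
    structure = np.zeros((3, 3, 3), bool)
    structure[1] = True
    structure[0, 1, 1] = structure[2, 1, 1] = True
    labels, n_labels = ndimage.label(detected, structure=structure)

    # temporal persistence filter: noise excursions last a frame or two,
    # genuine contacts persist; drop labels spanning too few frames
    min_pers = min(config.min_persistence_frames, data.shape[0])
    if n_labels and min_pers > 1:
        keep_ids = []
        for lab in range(1, n_labels + 1):
            frames = np.unique(np.nonzero(labels == lab)[0])
            if len(frames) >= min_pers:
                keep_ids.append(lab)
        remap = np.zeros(n_labels + 1, labels.dtype)
        for new, old in enumerate(keep_ids, start=1):
            remap[old] = new
        labels = remap[labels]

    mapping: dict[int, int] = {}
    if cell_labels is not None:
        for lab in np.unique(labels):
            if lab == 0:
                continue
            owners = cell_labels.labels[labels == lab]
            owners = owners[owners > 0]
            mapping[int(lab)] = int(np.bincount(owners).argmax()) if len(owners) else 0
    return LabelVolume(
        labels.astype(np.int32),
        "close_contact",
        glyco_video.pixel_size_um,
        glyco_video.frame_interval_s,
        mapping,
    )
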