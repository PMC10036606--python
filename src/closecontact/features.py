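"""Per-cell interaction events, stage assignment, and per-contact features.

A cell's encounter with the bilayer is summarized by five event times
(first membrane signal, adhesion, first close contact, calcium triggering,
maximum footprint area) which delimit the four interaction stages:
I "searching", II "scanning", III "spreading", IV "synapsing".  Each close
contact yields a per-timepoint record of its area, glycocalyx exclusion
(``exclusion_10 = 1 - p10(inside) / mean(outline)``), accumulated contact
time, and the stage its cell is in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .calcium import CellTrack, TriggerResult, classify_adhesion, detect_trigger
from .segmentation import LabelVolume
from .video import ImageVideo

EVENT_COLUMNS = [
    "time_CZ_first (s)",
    "time_adhesion (s)",
    "time_CCZ_first (s)",
    "time_Ca (s)",
    "time_to_CZ_max (s)",
]

STAGE_NAMES = {0: "", 1: "I searching", 2: "II scanning", 3: "III spreading", 4: "IV synapsing"}


@dataclass
class CellCalciumTrace:
    cell_id: int
    first_frame: int
    intensities: np.ndarray  # one value per frame of the cell's lifetime
    centroids_px: np.ndarray  # (n, 2), interpolated where missing
    interpolated: np.ndarray  # bool flags
    trigger: TriggerResult | None
    frame_interval_s: float

    @property
    def trigger_time_abs_s(self) -> float | None:
        if self.trigger is None or not self.trigger.triggered:
            return None
        return self.first_frame * self.frame_interval_s + self.trigger.trigger_time_s


def _cell_centroids(cell_labels: LabelVolume, cell_id: int):
    """Per-frame centroid of one cell, linearly interpolated over missing
    frames within the cell's lifetime.  Returns (first_frame, centroids,
    interpolated flags) or None if the cell never appears."""
    present = []
    cents = []
    for f in range(cell_labels.n_frames):
        mask = cell_labels.labels[f] == cell_id
        if mask.any():
            present.append(f)
            cents.append(ndimage.center_of_mass(mask))
    if not present:
        return None
    first, last = present[0], present[-1]
    frames = np.arange(first, last + 1)
    cents = np.asarray(cents)
    interp_y = np.interp(frames, present, cents[:, 0])
    interp_x = np.interp(frames, present, cents[:, 1])
    interpolated = ~np.isin(frames, present)
    return first, np.column_stack([interp_y, interp_x]), interpolated


def measure_cell_calcium(
    calcium_video: ImageVideo,
    cell_labels: LabelVolume,
    circle_radius_um: float = 5.0,
    **trigger_kwargs,
) -> dict[int, CellCalciumTrace]:
    """Mean calcium intensity in a circle at each cell's per-frame centroid.

    Centroids missing at intermediate timepoints are linearly interpolated
    from the neighbouring ones.  The resulting trace gets the same trigger
    analysis as the bulk calcium assay.
    """
    px = calcium_video.pixel_size_um
    r_px = circle_radius_um / px
    ny, nx = calcium_video.data.shape[1:]
    yy, xx = np.mgrid[0:ny, 0:nx]
    out: dict[int, CellCalciumTrace] = {}
    for cid in cell_labels.label_ids():
        res = _cell_centroids(cell_labels, int(cid))
        if res is None:
            warnings.warn(f"cell {cid} absent from all frames; skipped")
            continue
        first, cents, interp = res
        trace = np.empty(len(cents))
        for k, (cy, cx) in enumerate(cents):
            circle = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
            trace[k] = calcium_video.data[first + k][circle].mean()
        try:
            trig = detect_trigger(
                trace, frame_interval_s=calcium_video.frame_interval_s, **trigger_kwargs
            )
        except ValueError:
            trig = None
        out[int(cid)] = CellCalciumTrace(
            int(cid), first, trace, cents, interp, trig, calcium_video.frame_interval_s
        )
    return out


def qc_edge_exclusion(
    cell_labels: LabelVolume,
    trigger_times_s: dict[int, float | None],
    first_contact_times_s: dict[int, float | None],
    margin_px: int = 1,
    window_s: float = 300.0,
) -> tuple[list[int], list[int]]:
    """Flag cells that touch the field-of-view edge during their analysis
    window: before triggering, or — for non-triggering cells — within
    ``window_s`` after their first close contact.  Returns (kept, excluded)
    cell id lists."""
    dt = cell_labels.frame_interval_s
    ny, nx = cell_labels.labels.shape[1:]
    border = np.zeros((ny, nx), bool)
    border[:margin_px, :] = border[-margin_px:, :] = True
    border[:, :margin_px] = border[:, -margin_px:] = True
    kept, excluded = [], []
    for cid in cell_labels.label_ids():
        cid = int(cid)
        t_trig = trigger_times_s.get(cid)
        t_cc = first_contact_times_s.get(cid)
        if t_trig is not None:
            t_end = t_trig
        elif t_cc is not None:
            t_end = t_cc + window_s
        else:
            t_end = cell_labels.n_frames * dt
        bad = False
        for f in range(cell_labels.n_frames):
            if f * dt > t_end:
                break
            if (cell_labels.labels[f][border] == cid).any():
                bad = True
                break
        (excluded if bad else kept).append(cid)
    return kept, excluded


def _membrane_area_trace(cell_labels: LabelVolume, cell_id: int) -> np.ndarray:
    counts = np.array(
        [(cell_labels.labels[f] == cell_id).sum() for f in range(cell_labels.n_frames)],
        float,
    )
    return counts * cell_labels.pixel_area_um2


def detect_events(
    cell_labels: LabelVolume,
    contact_labels: LabelVolume,
    traces: dict[int, CellCalciumTrace],
    speed_threshold_um_s: float = 0.2,
    area_smooth_frames: int = 5,
) -> pd.DataFrame:
    """Per-cell interaction event table.

    ``time_to_CZ_max`` is taken from the maximum of the mean-filter-smoothed
    membrane-area trace; adhesion reuses the bulk-assay speed criterion on
    the centroid track.  Absent events are recorded as NaN.
    """
    dt = cell_labels.frame_interval_s
    rows = []
    for cid in cell_labels.label_ids():
        cid = int(cid)
        res = _cell_centroids(cell_labels, cid)
        if res is None:
            continue
        first, cents, _ = res
        t_cz = first * dt

        t_adh = np.nan
        if len(cents) >= 2:
            track = CellTrack(cid, first, cents * cell_labels.pixel_size_um,
                              np.zeros(len(cents)), dt)
            adh = classify_adhesion(track, speed_threshold_um_s)
            if adh.adhered:
                t_adh = first * dt + adh.adhesion_time_s

        t_cc = np.nan
        own = [lab for lab, owner in contact_labels.contact_to_cell.items() if owner == cid]
        if not contact_labels.contact_to_cell:
            own = list(contact_labels.label_ids())
        if own:
            frames = np.where(np.isin(contact_labels.labels, own).any(axis=(1, 2)))[0]
            if len(frames):
                t_cc = frames[0] * dt

        t_ca = np.nan
        tr = traces.get(cid)
        if tr is not None and tr.trigger_time_abs_s is not None:
            t_ca = tr.trigger_time_abs_s

        area = _membrane_area_trace(cell_labels, cid)
        smooth = ndimage.uniform_filter1d(area, min(area_smooth_frames, len(area)),
                                          mode="nearest")
        t_max = float(np.argmax(smooth)) * dt

        rows.append({
            "cell_id": cid,
            EVENT_COLUMNS[0]: t_cz,
            EVENT_COLUMNS[1]: t_adh,
            EVENT_COLUMNS[2]: t_cc,
            EVENT_COLUMNS[3]: t_ca,
            EVENT_COLUMNS[4]: t_max,
        })
    return pd.DataFrame(rows)


def assign_stages(
    events_row: pd.Series | dict,
    n_frames: int,
    frame_interval_s: float,
) -> np.ndarray:
    """Per-frame stage labels (0 = before any signal, 1..4 = stages I-IV).

    Intervals are half-open ``[event, next_event)``; stages III and IV are
    only assigned when the cell triggered.  Out-of-order events are clipped
    to the previous boundary with a warning.
    """
    t = np.arange(n_frames) * frame_interval_s
    get = events_row.get if isinstance(events_row, dict) else events_row.__getitem__

    def _val(col):
        try:
            v = get(col)
        except KeyError:
            return None
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    e1 = _val(EVENT_COLUMNS[0])
    e2 = _val(EVENT_COLUMNS[2])
    e3 = _val(EVENT_COLUMNS[3])
    e4 = _val(EVENT_COLUMNS[4])

    stages = np.zeros(n_frames, int)
    if e1 is None:
        return stages
    bounds = [e1]
    if e2 is not None:
        if e2 < bounds[-1]:
            warnings.warn("first close contact precedes first membrane signal; clipped")
            e2 = bounds[-1]
        bounds.append(e2)
        if e3 is not None:  # stages III/IV require triggering
            if e3 < bounds[-1]:
                warnings.warn("trigger precedes first close contact; clipped")
                e3 = bounds[-1]
            bounds.append(e3)
            if e4 is not None:
                if e4 < bounds[-1]:
                    warnings.warn("footprint maximum precedes trigger; clipped")
                    e4 = bounds[-1]
                bounds.append(e4)
    for s, b in enumerate(bounds, start=1):
        stages[t >= b] = s
    return stages


def contact_features(
    contact_labels: LabelVolume,
    glyco_video: ImageVideo,
    cell_labels: LabelVolume | None = None,
    stages_by_cell: dict[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-contact per-timepoint feature records.

    ``Area (μm^2)`` is the segmented pixel count times the pixel area;
    ``exclusion_10`` is 1 minus the 10th percentile of the (flat-field
    corrected) glycocalyx intensity inside the contact over the mean
    intensity on the one-pixel-wide outline of the owning cell's segmented
    membrane; ``contact_time (s)`` accumulates over temporally overlapping
    detections (the 3-D contact label).
    """
    px_area = contact_labels.pixel_area_um2
    dt = contact_labels.frame_interval_s
    rows = []
    for lab in contact_labels.label_ids():
        lab = int(lab)
        owner = contact_labels.contact_to_cell.get(lab, 0)
        frames = np.where((contact_labels.labels == lab).any(axis=(1, 2)))[0]
        for k, f in enumerate(frames):
            inside = contact_labels.labels[f] == lab
            area = inside.sum() * px_area
            excl = np.nan
            valid = True
            if cell_labels is not None:
                if owner:
                    cmask = cell_labels.labels[f] == owner
                else:
                    cmask = cell_labels.labels[f] > 0
                outline = cmask & ~ndimage.binary_erosion(cmask)
                if outline.any():
                    p10 = np.percentile(glyco_video.data[f][inside], 10)
                    excl = 1.0 - p10 / glyco_video.data[f][outline].mean()
                else:
                    valid = False
            stage = 0
            if stages_by_cell and owner in stages_by_cell:
                stage = int(stages_by_cell[owner][f])
            rows.append({
                "contact_id": lab,
                "cell_id": owner,
                "frame": int(f),
                "time_s": f * dt,
                "Area (μm^2)": area,
                "exclusion_10": excl,
                "contact_time (s)": k * dt,
                "stage": STAGE_NAMES.get(stage, ""),
                "valid": valid,
            })
    return pd.DataFrame(rows)


def contact_area_fraction(
    records: pd.DataFrame,
    trigger_time_s: float | None,
    cell_surface_area_um2: float,
    cell_id: int | None = None,
    frame_interval_s: float | None = None,
) -> float:
    """Total close-contact area at the moment of triggering divided by the
    cell's total membrane surface area (measured in solution)."""
    if trigger_time_s is None:
        raise ValueError("cell never triggered; fraction undefined")
    if cell_surface_area_um2 <= 0:
        raise ValueError("surface area must be positive")
    sel = records
    if cell_id is not None:
        sel = sel[sel["cell_id"] == cell_id]
    if not len(sel):
        return 0.0
    # contacts live at the frame containing the trigger time
    dt = frame_interval_s
    if dt is None:
        stepped = sel[sel["frame"] > 0]
        dt = float((stepped["time_s"] / stepped["frame"]).iloc[0]) if len(stepped) else 1.0
    target = round(trigger_time_s / dt)
    total = sel[sel["frame"] == target]["Area (μm^2)"].sum()
    return float(total / cell_surface_area_um2)
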