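"""Tests of per-cell calcium measurement, QC, event detection, stage
assignment and contact-feature extraction."""

import numpy as np
import pandas as pd
import pytest
from helpers_oracles import oracle_blur_bin, sort_percentile

from closecontact import (
    CameraModel,
    ContactTruth,
    GroundTruthScene,
    ImageVideo,
    LabelVolume,
    PSFModel,
    assign_stages,
    constant_cell,
    contact_area_fraction,
    contact_features,
    detect_events,
    make_ground_truth_frame,
    measure_cell_calcium,
    qc_edge_exclusion,
    simulate_video,
)
from closecontact.features import EVENT_COLUMNS

PX = 0.107
DT = 2.0


def _disc(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _cell_volume(n_frames=10, shape=(60, 60), cy=30, cx=30, r=20, missing=()):
    labels = np.zeros((n_frames, *shape), int)
    for f in range(n_frames):
        if f not in missing:
            labels[f][_disc(shape, cy, cx, r)] = 1
    return LabelVolume(labels, "cell", PX, DT)


class TestMeasureCellCalcium:
    def test_uniform_channel_constant_trace(self):
        vid = ImageVideo(np.full((10, 60, 60), 7.0), PX, DT)
        traces = measure_cell_calcium(vid, _cell_volume(), circle_radius_um=1.0)
        assert set(traces) == {1}
        np.testing.assert_allclose(traces[1].intensities, 7.0)

    def test_missing_centroid_interpolated_at_midpoint(self):
        labels = np.zeros((7, 60, 60), int)
        for f in range(7):
            if f == 5:
                continue
            shift = 2 * f  # cell drifts in y
            labels[f][_disc((60, 60), 20 + shift, 30, 8)] = 1
        lv = LabelVolume(labels, "cell", PX, DT)
        vid = ImageVideo(np.full((7, 60, 60), 5.0), PX, DT)
        traces = measure_cell_calcium(vid, lv, circle_radius_um=0.5)
        tr = traces[1]
        assert tr.interpolated[5]
        mid = 0.5 * (tr.centroids_px[4] + tr.centroids_px[6])
        np.testing.assert_allclose(tr.centroids_px[5], mid, atol=1e-6)

    def test_painted_step_trace_recovers_trigger_time(self):
        trigger_s = 60.0
        n_frames = 60
        scene = GroundTruthScene(
            field_size_um=(10, 10), n_frames=n_frames, frame_interval_s=DT,
            cells=[constant_cell((5, 5), 3.0, n_frames, trigger_s=trigger_s,
                                frame_interval_s=DT)],
        )
        res = simulate_video(scene, rng_seed=2)
        shape = res["calcium"].data.shape[1:]
        labels = np.zeros((n_frames, *shape), int)
        foot = _disc(shape, 5 / PX - 0.5, 5 / PX - 0.5, 3.0 / PX)
        labels[:, foot] = 1
        lv = LabelVolume(labels, "cell", PX, DT)
        traces = measure_cell_calcium(res["calcium"], lv, circle_radius_um=3.0)
        t = traces[1].trigger_time_abs_s
        assert t is not None
        assert abs(t - trigger_s) <= DT


class TestQCEdgeExclusion:
    def test_interior_cell_kept(self):
        kept, excl = qc_edge_exclusion(_cell_volume(), {1: 10.0}, {1: 4.0})
        assert kept == [1] and excl == []

    def test_border_touch_before_trigger_excluded(self):
        lv = _cell_volume(cy=5, cx=30, r=10)  # touches top edge every frame
        kept, excl = qc_edge_exclusion(lv, {1: 10.0}, {1: 4.0})
        assert excl == [1]

    def test_late_border_touch_of_nontrigger_cell_kept(self):
        labels = np.zeros((10, 60, 60), int)
        for f in range(10):
            if f < 8:
                labels[f][_disc((60, 60), 30, 30, 10)] = 1
            else:
                labels[f][_disc((60, 60), 5, 30, 10)] = 1  # touches edge late
        lv = LabelVolume(labels, "cell", PX, DT)
        # no trigger; first contact at 0 s; window of 10 s ends before frame 8
        kept, excl = qc_edge_exclusion(lv, {1: None}, {1: 0.0}, window_s=10.0)
        assert kept == [1]


class TestDetectEvents:
    def _contact_volume(self, n_frames=10, first_frame=0, shape=(60, 60)):
        labels = np.zeros((n_frames, *shape), int)
        for f in range(first_frame, n_frames):
            labels[f][_disc(shape, 30, 30, 2)] = 1
        return LabelVolume(labels, "close_contact", PX, DT, {1: 1})

    def test_no_trigger_time_ca_absent(self):
        cells = _cell_volume()
        contacts = self._contact_volume()
        events = detect_events(cells, contacts, traces={})
        row = events.iloc[0]
        assert np.isnan(row[EVENT_COLUMNS[3]])
        assert row[EVENT_COLUMNS[0]] == 0.0
        assert row[EVENT_COLUMNS[2]] == 0.0

    def test_growing_membrane_max_at_last_frame(self):
        labels = np.zeros((10, 60, 60), int)
        for f in range(10):
            labels[f][_disc((60, 60), 30, 30, 5 + f)] = 1
        cells = LabelVolume(labels, "cell", PX, DT)
        events = detect_events(cells, self._contact_volume(), traces={})
        assert events.iloc[0][EVENT_COLUMNS[4]] == pytest.approx(9 * DT)

    def test_scripted_first_contact_time(self):
        events = detect_events(_cell_volume(), self._contact_volume(first_frame=4),
                               traces={})
        assert events.iloc[0][EVENT_COLUMNS[2]] == pytest.approx(4 * DT)


class TestAssignStages:
    ROW = {
        EVENT_COLUMNS[0]: 0.0,
        EVENT_COLUMNS[2]: 20.0,
        EVENT_COLUMNS[3]: 60.0,
        EVENT_COLUMNS[4]: 120.0,
    }

    def test_four_stage_assignment(self):
        stages = assign_stages(self.ROW, n_frames=16, frame_interval_s=10.0)
        # frames at 10/40/90/150 s
        assert stages[1] == 1 and stages[4] == 2 and stages[9] == 3 and stages[15] == 4

    def test_no_trigger_only_stages_one_two(self):
        row = dict(self.ROW)
        row[EVENT_COLUMNS[3]] = np.nan
        stages = assign_stages(row, n_frames=16, frame_interval_s=10.0)
        assert set(stages) <= {0, 1, 2}

    def test_trigger_on_frame_boundary_is_stage_three(self):
        stages = assign_stages(self.ROW, n_frames=16, frame_interval_s=10.0)
        assert stages[6] == 3  # frame exactly at 60 s

    def test_monotone_and_gapless(self):
        stages = assign_stages(self.ROW, n_frames=100, frame_interval_s=2.0)
        diffs = np.diff(stages)
        assert np.all(diffs >= 0)
        present = sorted(set(stages[stages > 0]))
        assert present == list(range(1, len(present) + 1))

    def test_out_of_order_events_clipped(self):
        row = dict(self.ROW)
        row[EVENT_COLUMNS[3]] = 10.0  # trigger before first contact
        with pytest.warns(UserWarning):
            stages = assign_stages(row, n_frames=16, frame_interval_s=10.0)
        assert np.all(np.diff(stages) >= 0)


class TestContactFeatures:
    def _volumes(self, glyco, contact_mask, cell_mask, n_frames=1):
        cl = np.zeros((n_frames, *glyco.shape[-2:]), int)
        cv = np.zeros_like(cl)
        cl[:, contact_mask] = 1
        cv[:, cell_mask] = 1
        contacts = LabelVolume(cl, "close_contact", PX, DT, {1: 1})
        cells = LabelVolume(cv, "cell", PX, DT)
        vid = ImageVideo(np.broadcast_to(glyco, (n_frames, *glyco.shape[-2:])).copy(),
                         PX, DT)
        return contacts, vid, cells

    def test_constant_exclusion_case(self):
        shape = (40, 40)
        contact = _disc(shape, 20, 20, 3)
        cell = _disc(shape, 20, 20, 15)
        img = np.full(shape, 100.0)
        img[contact] = 60.0
        contacts, vid, cells = self._volumes(img, contact, cell)
        rec = contact_features(contacts, vid, cells)
        assert rec.iloc[0]["exclusion_10"] == pytest.approx(0.40)
        assert rec.iloc[0]["Area (μm^2)"] == pytest.approx(contact.sum() * PX**2)

    def test_identical_inside_outside_zero_exclusion(self):
        shape = (40, 40)
        contact = _disc(shape, 20, 20, 3)
        cell = _disc(shape, 20, 20, 15)
        img = np.full(shape, 80.0)
        contacts, vid, cells = self._volumes(img, contact, cell)
        rec = contact_features(contacts, vid, cells)
        assert rec.iloc[0]["exclusion_10"] == pytest.approx(0.0, abs=1e-9)

    def test_percentile_matches_sort_oracle(self):
        shape = (30, 30)
        contact = np.zeros(shape, bool)
        contact[10, 10:20] = True  # 10 pixels
        cell = _disc(shape, 15, 15, 12)
        img = np.full(shape, 100.0)
        img[10, 10:20] = np.arange(50, 150, 10, dtype=float)
        contacts, vid, cells = self._volumes(img, contact, cell)
        rec = contact_features(contacts, vid, cells)
        outline = cell & ~_disc(shape, 15, 15, 11)
        expected = 1 - sort_percentile(img[10, 10:20], 10) / 100.0
        assert rec.iloc[0]["exclusion_10"] == pytest.approx(expected, abs=1e-9)

    def test_contact_time_increments_per_frame(self):
        shape = (40, 40)
        contact = _disc(shape, 20, 20, 3)
        cell = _disc(shape, 20, 20, 15)
        img = np.full(shape, 100.0)
        contacts, vid, cells = self._volumes(img, contact, cell, n_frames=5)
        rec = contact_features(contacts, vid, cells)
        np.testing.assert_allclose(np.diff(rec["contact_time (s)"]), DT)

    def test_per_frame_contact_count_conserved(self):
        shape = (50, 50)
        cl = np.zeros((3, *shape), int)
        cl[:, _disc(shape, 15, 15, 3)] = 1
        cl[:, _disc(shape, 35, 35, 3)] = 2
        contacts = LabelVolume(cl, "close_contact", PX, DT, {1: 1, 2: 1})
        vid = ImageVideo(np.full((3, *shape), 100.0), PX, DT)
        rec = contact_features(contacts, vid, None)
        for f in range(3):
            assert len(rec[rec["frame"] == f]) == 2

    def test_exclusion_matches_blurred_convolution_oracle(self):
        # noise-free rendered scene; oracle blurs the ground truth with an
        # independent dense convolution and applies the same statistic
        cam, psf = CameraModel(), PSFModel()
        depth, diam = 0.6, 0.5
        scene = GroundTruthScene(
            field_size_um=(4.28, 4.28),
            contacts=[ContactTruth((2.14, 2.14), diam, depth)],
            n_frames=1,
        )
        res = simulate_video(scene, rng_seed=0, noise=False)
        glyco = res["glycocalyx"]
        shape = glyco.data.shape[1:]
        c_px = 2.14 / PX - 0.5
        contact = _disc(shape, c_px, c_px, diam / 2 / PX)
        cell = _disc(shape, c_px, c_px, 1.5 / PX)
        contacts, _, cells = self._volumes(glyco.data[0], contact, cell)
        rec = contact_features(contacts, glyco, cells)

        truth = make_ground_truth_frame(scene, 0.0, cam.pixel_size_nm / 20, cam)
        oracle_img = oracle_blur_bin(truth, psf.sigma_nm, cam.pixel_size_nm / 20, 20)
        oracle_img = oracle_img * cam.quantum_efficiency
        from scipy import ndimage as ndi

        outline = cell & ~ndi.binary_erosion(cell)
        oracle_excl = 1 - sort_percentile(oracle_img[contact], 10) / oracle_img[outline].mean()
        assert rec.iloc[0]["exclusion_10"] == pytest.approx(oracle_excl, abs=0.05)


class TestContactAreaFraction:
    def _records(self, areas, frame=5):
        return pd.DataFrame([
            {"contact_id": i + 1, "cell_id": 1, "frame": frame,
             "time_s": frame * DT, "Area (μm^2)": a}
            for i, a in enumerate(areas)
        ])

    def test_simple_division(self):
        rec = self._records([0.4, 0.6])
        frac = contact_area_fraction(rec, trigger_time_s=5 * DT,
                                     cell_surface_area_um2=500.0)
        assert frac == pytest.approx(1.0 / 500.0)

    def test_zero_contacts_at_trigger(self):
        rec = self._records([0.5], frame=2)
        frac = contact_area_fraction(rec, trigger_time_s=16.0,
                                     cell_surface_area_um2=500.0)
        assert frac == 0.0

    def test_no_trigger_undefined(self):
        with pytest.raises(ValueError):
            contact_area_fraction(self._records([1.0]), None, 500.0)
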