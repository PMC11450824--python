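"""Seeded watershed, z-propagation, time tracking and nucleus segmentation
checked against generator ground truth."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import mean_iou
from nucleoscope import segmentation as seg
from nucleoscope.synthetic import (
    DynamicsSpec,
    EmbryoSpec,
    NucleusSpec,
    generate_embryo,
)

PIX = 0.16


@pytest.fixture(scope="module")
def segmented(static_embryo):
    spec, volume, truth = static_embryo
    ref_z = 11
    ref = seg.segment_cells_seeded(volume.data[0], ref_z, pixel=PIX)
    lab3d, flagged = seg.propagate_z(ref, volume.data[0], ref_z, pixel=PIX)
    nuc3d = seg.segment_nuclei(lab3d, volume.channel("nuclei")[0])
    return spec, truth, ref, lab3d, nuc3d, flagged


def test_watershed_recovers_grid_cells(segmented):
    spec, truth, ref, *_ = segmented
    assert len(np.unique(ref)) - 1 == 9
    assert mean_iou(ref, truth.cell_labels.labels[0][11]) >= 0.95


def test_watershed_tiles_footprint_without_interior_holes(segmented):
    # cell labels at the reference layer cover the tissue footprint: any
    # unlabeled pixel inside the convex tissue region would be a hole
    spec, truth, ref, *_ = segmented
    gt = truth.cell_labels.labels[0][11] > 0
    interior = ndi.binary_erosion(gt, iterations=3)
    assert (ref[interior] > 0).all()


def test_overseeding_is_flagged_by_area_outlier_report(static_embryo):
    spec, volume, truth = static_embryo
    gt = truth.cell_labels.labels[0][11]
    centers = [ndi.center_of_mass(gt == t) for t in range(1, 10)]
    seeds = [(int(r), int(c)) for r, c in centers]
    seeds.append((seeds[4][0] + 8, seeds[4][1] + 8))  # second seed in cell 5
    lab = seg.segment_cells_seeded(volume.data[0], 11, np.array(seeds), pixel=PIX)
    report = seg.area_outlier_report(lab, PIX)
    assert report["flag_small"].sum() >= 1


def test_watershed_on_flat_image_gives_voronoi_cover():
    frame = np.ones((1, 1, 64, 64), dtype=float)
    seeds = np.array([[16, 16], [48, 48], [16, 48]])
    lab = seg.segment_cells_seeded(frame, 0, seeds, pixel=PIX, background="none")
    assert (lab > 0).all()
    assert len(np.unique(lab)) == 3


def test_too_few_seeds_or_empty_frame_raise():
    frame = np.zeros((1, 1, 32, 32))
    with pytest.raises(ValueError, match="empty frame"):
        seg.segment_cells_seeded(frame, 0, np.array([[4, 4], [20, 20]]))
    with pytest.raises(ValueError, match="at least 2 seeds"):
        seg.segment_cells_seeded(np.ones((1, 1, 32, 32)), 0, np.array([[4, 4]]))


def test_propagation_tracks_prism_centroids():
    # straight prisms (no per-layer jitter): per-z centroid drift <= 1 px
    # between adjacent layers
    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=1, seed=4, jitter=0.0)
    volume, truth = generate_embryo(spec, dynamics=DynamicsSpec(osc_rel_amplitude=0.0))
    ref = seg.segment_cells_seeded(volume.data[0], 11, pixel=PIX)
    lab3d, _ = seg.propagate_z(ref, volume.data[0], 11, pixel=PIX)
    for track in (1, 5, 9):
        cents = []
        # use the segmentation label that covers this ground-truth cell
        m11 = truth.cell_labels.labels[0][11] == track
        vals, counts = np.unique(lab3d[11][m11], return_counts=True)
        lab_id = vals[np.argmax(counts)]
        # skip the brightened apical cap layer, whose relief differs
        for z in range(spec.apical_z + 1, spec.n_z):
            mz = lab3d[z] == lab_id
            if mz.any():
                cents.append(ndi.center_of_mass(mz))
        d = np.diff(np.asarray(cents), axis=0)
        assert (np.hypot(d[:, 0], d[:, 1]) <= 1.0).all()


def test_propagation_follows_prescribed_tilt():
    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=1, seed=7, tilt=(0.0, 0.05))
    dyn = DynamicsSpec(osc_rel_amplitude=0.0)
    volume, truth = generate_embryo(spec, dynamics=dyn)
    ref_z = 11
    ref = seg.segment_cells_seeded(volume.data[0], ref_z, pixel=PIX)
    lab3d, _ = seg.propagate_z(ref, volume.data[0], ref_z, pixel=PIX)
    m11 = truth.cell_labels.labels[0][ref_z] == 5
    vals, counts = np.unique(lab3d[ref_z][m11], return_counts=True)
    lab_id = vals[np.argmax(counts)]
    x_ref = ndi.center_of_mass(lab3d[ref_z] == lab_id)[1]
    for z in (spec.apical_z + 2, spec.apical_z + 17):
        x = ndi.center_of_mass(lab3d[z] == lab_id)[1]
        expected = x_ref + 0.05 * (z - ref_z) / PIX * spec.voxel_size[0]
        assert abs(x - expected) <= 2.0


def test_single_layer_propagation_is_identity():
    spec = EmbryoSpec(grid_shape=(2, 2), n_frames=1, seed=3)
    volume, _ = generate_embryo(spec, dynamics=DynamicsSpec(osc_rel_amplitude=0.0))
    ref_z = 11
    ref = seg.segment_cells_seeded(volume.data[0], ref_z, pixel=PIX)
    frame = volume.data[0][ref_z : ref_z + 1]
    out, _ = seg.propagate_z(ref, frame, 0, pixel=PIX)
    assert np.array_equal(out[0], ref)


def test_static_movie_tracks_persist():
    spec = EmbryoSpec(grid_shape=(2, 2), n_frames=4, seed=3)
    _, truth = generate_embryo(spec, dynamics=DynamicsSpec(osc_rel_amplitude=0.0))
    ref = truth.cell_labels.labels[:, 11]
    tracked, events = seg.track_time(ref)
    for track, start in events.starts.items():
        assert start == 0
        assert events.ends[track] == 3
    assert np.array_equal(tracked, ref)


def test_deleted_cell_ends_exactly_one_track():
    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=6, seed=3)
    dyn = DynamicsSpec(
        osc_rel_amplitude=0.0,
        extrusions=[(5, 0.5)],
        extrusion_loss_depth=1e6,  # full deletion at all depths
    )
    _, truth = generate_embryo(spec, dynamics=dyn)
    ref = truth.cell_labels.labels[:, 11]
    tracked, events = seg.track_time(ref)
    ended_early = [t for t, e in events.ends.items() if e < 5]
    assert len(ended_early) == 1


def test_t1_tracks_persist_through_exchange():
    from nucleoscope.synthetic import T1EventSpec

    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=8, seed=3, frame_interval=120.0)
    dyn = DynamicsSpec(
        t1_events=[T1EventSpec(quartet=(4, 5, 1, 7), rate=-0.4)],
        osc_rel_amplitude=0.0,
        osc_frequency=0.0,
    )
    _, truth = generate_embryo(spec, dynamics=dyn)
    ref = truth.cell_labels.labels[:, 11]
    tracked, events = seg.track_time(ref)
    for track in (4, 5, 1, 7):
        assert events.ends[track] == 7


def test_nucleus_volume_within_5pct_of_analytic(segmented):
    spec, truth, ref, lab3d, nuc3d, _ = segmented
    c, b, a = NucleusSpec().semi_axes
    analytic = 4.0 / 3.0 * math.pi * a * b * c
    vox = np.prod(spec.voxel_size)
    vols = [(nuc3d == t).sum() * vox for t in np.unique(nuc3d) if t > 0]
    assert len(vols) == 9
    assert np.mean(vols) == pytest.approx(analytic, rel=0.05)


def test_nucleus_labels_inherit_host_cell_label(segmented):
    spec, truth, ref, lab3d, nuc3d, _ = segmented
    inside = nuc3d > 0
    assert (lab3d[inside] == nuc3d[inside]).mean() > 0.98


def test_zero_nuclear_channel_gives_absent_nucleus(segmented):
    spec, truth, ref, lab3d, *_ = segmented
    empty = np.zeros_like(lab3d, dtype=float)
    out = seg.segment_nuclei(lab3d, empty)
    assert (out == 0).all()


@pytest.mark.parametrize(
    "zs,expected",
    [
        (range(5, 15), 9.0),  # occupies z=5..14 at dz=1 -> 9 µm
        ([7], 0.0),  # single-plane nucleus
    ],
)
def test_nucleus_length_from_occupied_span(zs, expected):
    mask = np.zeros((20, 4, 4), dtype=bool)
    for z in zs:
        mask[z, 1:3, 1:3] = True
    assert seg.nucleus_length(mask, dz=1.0) == expected


def test_nucleus_length_of_half_step_centered_ellipsoid():
    # c_z = 5 µm ellipsoid centred between z-layers spans ~10 µm within
    # one z-step (an exactly on-grid centre loses both boundary planes)
    zz, yy, xx = np.mgrid[0:24, 0:40, 0:40]
    r2 = ((zz - 11.5) / 5.0) ** 2 + ((yy - 20) / 12) ** 2 + ((xx - 20) / 12) ** 2
    mask = r2 <= 1.0
    assert seg.nucleus_length(mask, dz=1.0) == pytest.approx(10.0, abs=1.0)
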