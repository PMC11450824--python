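"""Interface geometry, T1 detection and contraction/extension rates on
scripted neighbour exchanges."""

import math

import numpy as np
import pandas as pd
import pytest

from nucleoscope import interfaces as ifc
from nucleoscope.synthetic import (
    DynamicsSpec,
    EmbryoSpec,
    T1EventSpec,
    TissueLattice,
    generate_plane_movie,
)

PIX = 0.16


@pytest.mark.parametrize(
    "dy,dx,expected",
    [
        (4.0, 0.0, 0.0),  # vertical (DV-aligned)
        (0.0, 4.0, 90.0),  # horizontal (AP-aligned)
        (4.0, 4.0, 45.0),
        (-4.0, 4.0, -45.0),
        (-4.0, 0.0, 0.0),  # direction sign must not matter
    ],
)
def test_angle_convention(dy, dx, expected):
    theta = ifc.fold_angle(math.degrees(math.atan2(dx, dy)))
    assert theta == pytest.approx(expected)


@pytest.fixture(scope="module")
def static_plane():
    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=1, seed=2)
    pm = generate_plane_movie(spec, DynamicsSpec(osc_rel_amplitude=0.0), depth_um=7.0)
    return pm


def test_hexagonal_lattice_interface_lengths_and_angles(static_plane):
    pm = static_plane
    table = ifc.build_interfaces(pm.labels[0], PIX)
    edge = pm.lattice.hexagon_edge  # 4.39 µm for the default pitch
    assert len(table) == 16  # 8 horizontal-pair + 8 diagonal-pair interfaces
    assert table["length_um"].between(edge - 0.6, edge + 0.6).all()
    vertical = table[table["angle_deg"].abs() <= 15]
    diagonal = table[table["angle_deg"].abs() > 15]
    assert len(vertical) == 6  # one vertical interface per row-adjacent pair
    assert np.allclose(vertical["angle_deg"].abs(), 0.0, atol=3.0)
    assert np.allclose(diagonal["angle_deg"].abs(), 60.0, atol=4.0)


def test_interface_symmetry_and_order_invariance(static_plane):
    # length is a property of the unordered pair
    table = ifc.build_interfaces(static_plane.labels[0], PIX)
    assert (table["a"] < table["b"]).all()
    assert not table.duplicated(subset=["a", "b"]).any()


def test_interface_length_bounded_by_vertex_path(static_plane):
    # Euclidean vertex distance cannot exceed the boundary-pixel count
    # times the pixel diagonal (discrete path upper bound)
    pm = static_plane
    lab = pm.labels[0]
    table = ifc.build_interfaces(lab, PIX)
    for _, r in table.iterrows():
        from nucleoscope.synthetic import _pair_boundary

        n_boundary = _pair_boundary(lab, int(r["a"]), int(r["b"])).sum()
        assert r["length_um"] <= n_boundary * PIX * math.sqrt(2.0)


def test_scripted_t1_detected_within_one_frame():
    spec = EmbryoSpec(grid_shape=(3, 4), n_frames=80, seed=3)
    dyn = DynamicsSpec(
        t1_events=[T1EventSpec(quartet=(5, 6, 1, 9), rate=-0.3)], osc_rel_amplitude=0.0
    )
    pm = generate_plane_movie(spec, dyn, depth_um=7.0)
    series = ifc.interface_series(pm.labels, PIX)
    events = ifc.detect_t1(series, spec.frame_interval)
    assert len(events) == 1
    ev = events[0]
    assert {ev.a, ev.b} == {5, 6} and {ev.c, ev.d} == {1, 9}
    truth_t2 = pm.t1_truth["t2_min"].iloc[0]
    assert abs(ev.t2_min - truth_t2) <= 2 * spec.frame_interval / 60.0
    assert not ev.rosette


def test_movie_without_t1_yields_no_events(static_plane):
    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=6, seed=2)
    pm = generate_plane_movie(spec, DynamicsSpec(osc_rel_amplitude=0.0), depth_um=7.0)
    series = ifc.interface_series(pm.labels, PIX)
    assert ifc.detect_t1(series, spec.frame_interval) == []


def test_two_overlapping_t1s_in_disjoint_quartets_both_detected():
    spec = EmbryoSpec(grid_shape=(3, 4), n_frames=80, seed=4)
    dyn = DynamicsSpec(
        t1_events=[
            T1EventSpec(quartet=(5, 6, 1, 9), rate=-0.3),
            T1EventSpec(quartet=(7, 8, 3, 11), rate=-0.35),
        ],
        osc_rel_amplitude=0.0,
    )
    pm = generate_plane_movie(spec, dyn, depth_um=7.0)
    series = ifc.interface_series(pm.labels, PIX)
    events = ifc.detect_t1(series, spec.frame_interval)
    assert {frozenset((e.a, e.b)) for e in events} == {frozenset((5, 6)), frozenset((7, 8))}


def test_t1_event_swaps_exactly_two_adjacency_edges():
    spec = EmbryoSpec(grid_shape=(3, 4), n_frames=2, seed=3, frame_interval=1500.0)
    dyn = DynamicsSpec(
        t1_events=[T1EventSpec(quartet=(5, 6, 1, 9), rate=-0.3)],
        osc_rel_amplitude=0.0,
        osc_frequency=0.0,
    )
    pm = generate_plane_movie(spec, dyn, depth_um=7.0)
    adj0 = ifc.label_adjacency(pm.labels[0])
    adj1 = ifc.label_adjacency(pm.labels[1])
    assert adj0 - adj1 == {(5, 6)}
    assert adj1 - adj0 == {(1, 9)}


def test_t1_windowed_rates_match_schedule_oracle():
    spec = EmbryoSpec(grid_shape=(3, 4), n_frames=101, seed=3)
    rate = -0.3
    dyn = DynamicsSpec(
        t1_events=[T1EventSpec(quartet=(5, 6, 1, 9), rate=rate)], osc_rel_amplitude=0.0
    )
    pm = generate_plane_movie(spec, dyn, depth_um=7.0)
    series = ifc.interface_series(pm.labels, PIX)
    ev = ifc.detect_t1(series, spec.frame_interval)[0]
    signed = ifc.signed_length_series(series, ev)
    measured = ifc.t1_rate_metrics(signed, ev.t2_frame, spec.frame_interval)

    # oracle: apply the endpoint definition to the scripted schedule
    tru = pm.t1_truth.set_index("frame")["signed_length_um"]
    w = int(round(10 * 60 / spec.frame_interval))
    oracle = (tru[ev.t2_frame + w] - tru[ev.t2_frame - w]) / 20.0
    assert measured["interface_rate_um_min"] == pytest.approx(oracle, abs=0.02)
    # symmetric linear schedule: the metric recovers the scripted slope
    assert measured["interface_rate_um_min"] == pytest.approx(rate, abs=0.02)


def test_t1_rate_missing_without_flanking_window():
    signed = pd.DataFrame({"t": np.arange(10), "signed_length_um": np.linspace(2, -2, 10)})
    out = ifc.t1_rate_metrics(signed, 5, frame_interval=15.0)
    assert math.isnan(out["interface_rate_um_min"])


def test_scripted_extension_rate_recovered():
    # a/b seeds scripted so their centroid distance grows at 0.2 µm/min,
    # without interface contraction (a contracting quartet adds its own
    # genuine extension on top of the scripted one)
    spec = EmbryoSpec(grid_shape=(3, 4), n_frames=41, seed=6)
    dyn = DynamicsSpec(
        t1_events=[T1EventSpec(quartet=(5, 6, 1, 9), rate=0.0, ab_separation_rate=0.2)],
        osc_rel_amplitude=0.0,
    )
    pm = generate_plane_movie(spec, dyn, depth_um=7.0)
    cd = ifc.centroid_distance_series(pm.labels, 5, 6, PIX)
    signed = pd.DataFrame({"t": cd["t"], "signed_length_um": 0.0})
    # measure over the early window where the scripted seed motion is
    # small relative to the lattice pitch (the Voronoi response is
    # calibrated in that linear regime)
    out = ifc.t1_rate_metrics(
        signed, 14, spec.frame_interval, centroid_distance=cd, window_min=3.0
    )
    assert out["extension_rate_um_min"] == pytest.approx(0.2, abs=0.02)


def test_t1_event_produces_positive_extension():
    spec = EmbryoSpec(grid_shape=(3, 4), n_frames=101, seed=6)
    dyn = DynamicsSpec(
        t1_events=[T1EventSpec(quartet=(5, 6, 1, 9), rate=-0.3)], osc_rel_amplitude=0.0
    )
    pm = generate_plane_movie(spec, dyn, depth_um=7.0)
    series = ifc.interface_series(pm.labels, PIX)
    ev = ifc.detect_t1(series, spec.frame_interval)[0]
    signed = ifc.signed_length_series(series, ev)
    cd = ifc.centroid_distance_series(pm.labels, ev.a, ev.b, PIX)
    out = ifc.t1_rate_metrics(signed, ev.t2_frame, spec.frame_interval, centroid_distance=cd)
    assert out["extension_rate_um_min"] > 0.05


@pytest.mark.parametrize(
    "l0,l1,expected",
    [(6.0, 0.0, -0.3), (4.0, 4.0, 0.0), (6.0, -2.0, -0.4)],
)
def test_vertical_interface_rate_arithmetic(l0, l1, expected):
    signed = pd.DataFrame(
        {"t": np.arange(81), "signed_length_um": np.linspace(l0, l1, 81)}
    )
    rate = ifc.vertical_interface_rate(signed, 0.0, 20.0, frame_interval=15.0)
    assert rate == pytest.approx(expected)


def test_directionality_mass_concentrates_on_contracting_verticals():
    # only vertical interfaces contract: >= 90% of histogram mass in |θ|<=15°
    spec = EmbryoSpec(grid_shape=(3, 4), n_frames=41, seed=8)
    dyn = DynamicsSpec(
        t1_events=[
            T1EventSpec(quartet=(5, 6, 1, 9), rate=-0.6),
            T1EventSpec(quartet=(7, 8, 3, 11), rate=-0.6),
        ],
        osc_rel_amplitude=0.0,
    )
    pm = generate_plane_movie(spec, dyn, depth_um=7.0)
    series = ifc.interface_series(pm.labels, PIX)
    rates = ifc.interface_rates(series, spec.frame_interval)
    hist = ifc.directionality_histogram(rates, rate_threshold=-0.5)
    in_band = hist[(hist.bin_left_deg >= -15) & (hist.bin_right_deg <= 15)]["count"].sum()
    assert hist["count"].sum() >= 2
    assert in_band / hist["count"].sum() >= 0.9


def test_directionality_threshold_minus_inf_includes_all(static_plane):
    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=5, seed=2)
    pm = generate_plane_movie(spec, DynamicsSpec(osc_rel_amplitude=0.0), depth_um=7.0)
    series = ifc.interface_series(pm.labels, PIX)
    rates = ifc.interface_rates(series, spec.frame_interval)
    # a fully relaxed threshold (+inf for a rate <= threshold criterion)
    # keeps every interface
    hist = ifc.directionality_histogram(rates, rate_threshold=math.inf)
    assert hist["count"].sum() == len(rates.dropna(subset=["angle_deg"]))


def test_directionality_empty_selection_warns(static_plane):
    rates = pd.DataFrame({"a": [1], "b": [2], "rate_um_min": [0.5], "angle_deg": [0.0]})
    hist = ifc.directionality_histogram(rates, rate_threshold=-0.5)
    assert hist["count"].sum() == 0
    assert "warning" in hist.attrs
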