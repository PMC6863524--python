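"""Toolpath generation: templates, orientation schedule, layer slicing, support."""

import math

import numpy as np
import pytest

from scafslicer import (
    PatternMap,
    PorePattern,
    SUPPORT_LABEL,
    SliceOptions,
    build_template,
    generate_support,
    label_linear_gradient,
    make_fixture,
    orientation_schedule,
    slice_layer,
    slice_volume,
)


class TestTemplate:
    def test_single_fiber_strut_lattice(self):
        t = build_template(PorePattern(0.5, 1), "x")
        assert t.period == pytest.approx(1.0)
        assert t.fiber_offsets == (0.25,)
        assert t.fiber_positions(0.0, 4.0) == pytest.approx([0.25, 1.25, 2.25, 3.25])

    def test_multi_fiber_strut_spans_strut_width(self):
        pat = PorePattern(0.8, 4)
        t = build_template(pat, "y")
        assert t.period == pytest.approx(2.8)
        span = max(t.fiber_offsets) - min(t.fiber_offsets) + pat.nozzle_diameter
        assert span == pytest.approx(pat.strut_width)

    def test_deterministic(self):
        a = build_template(PorePattern(0.5, 2), "x", phase=1.0)
        b = build_template(PorePattern(0.5, 2), "x", phase=1.0)
        assert a == b

    def test_bad_orientation(self):
        with pytest.raises(ValueError):
            build_template(PorePattern(0.5, 1), "z")


class TestOrientationSchedule:
    def test_thin_pattern_alternates_every_layer(self):
        pat = PorePattern(0.2)  # one layer per strut
        assert [orientation_schedule(pat, i) for i in range(4)] == ["x", "y", "x", "y"]

    def test_tall_strut_repeats_before_rotating(self):
        pat = PorePattern(0.8)  # four layers per strut
        sched = [orientation_schedule(pat, i) for i in range(8)]
        assert sched == ["x"] * 4 + ["y"] * 4

    def test_layer_zero_is_x_for_any_pattern(self):
        for pore in (0.2, 0.35, 0.5, 0.8, 1.0):
            assert orientation_schedule(PorePattern(pore), 0) == "x"


def _oracle_fiber_positions(pattern, region_lo, region_hi, n_voxels, pitch):
    """Independent lattice enumeration: fibers kept where their width band
    covers at least one voxel center of [region_lo, region_hi)."""
    w = pattern.nozzle_diameter
    period = pattern.in_plane_period
    centers = region_lo + (np.arange(n_voxels) + 0.5) * pitch
    kept = []
    n = int(math.floor((region_lo - period) / period))
    while True:
        left = n * period
        if left > region_hi + period:
            break
        for i in range(pattern.strut_fiber_count):
            pos = left + (i + 0.5) * w
            if ((centers >= pos - w / 2 - 1e-9) & (centers < pos + w / 2 - 1e-9)).any():
                kept.append(pos)
        n += 1
    return kept


class TestSliceLayer:
    def test_full_square_single_fiber_struts(self, printer):
        """20 mm square, pore 0.5/strut 0.5: 20 struts of one 20 mm fiber."""
        vol = make_fixture("box", (20, 20, 10), 0.1)
        pm = PatternMap({1: PorePattern(0.5, 1)})
        layer = slice_layer(vol, pm, 0, printer)
        assert len(layer.segments) == 20
        assert all(s.length == pytest.approx(20.0) for s in layer.segments)
        assert all(s.start[1] == s.end[1] for s in layer.segments)  # x-oriented

    def test_segment_count_matches_lattice_oracle(self, printer):
        """Wide-strut pattern on the same square: count from an independent
        enumeration of lattice fibers whose band covers a voxel center."""
        pat = PorePattern(0.8, 4)
        vol = make_fixture("box", (20, 20, 10), 0.1)
        pm = PatternMap({1: pat})
        layer = slice_layer(vol, pm, 0, printer)
        expected = _oracle_fiber_positions(pat, 0.0, 20.0, 200, 0.1)
        assert len(layer.segments) == len(expected)
        got = sorted({s.start[1] for s in layer.segments})
        assert got == pytest.approx(sorted(expected))

    def test_level_outside_volume_is_empty(self, printer):
        vol = make_fixture("box", (5, 5, 2), 0.1)
        pm = PatternMap({1: PorePattern(0.5, 1)})
        assert len(slice_layer(vol, pm, 500, printer)) == 0

    def test_serpentine_alternation(self, printer):
        vol = make_fixture("box", (10, 10, 2), 0.1)
        pm = PatternMap({1: PorePattern(0.5, 1)})
        segs = slice_layer(vol, pm, 0, printer).segments
        directions = [np.sign(s.end[0] - s.start[0]) for s in segs]
        assert all(a == -b for a, b in zip(directions, directions[1:]))

    def test_min_fiber_length_drops_short_clips(self, printer):
        # a sliver region 0.6 mm long cannot host a 1.0 mm minimum fiber
        vol = make_fixture("box", (0.6, 10, 2), 0.1)
        pm = PatternMap({1: PorePattern(0.5, 1)})
        layer = slice_layer(vol, pm, 0, printer)  # layer 0 is x-oriented
        assert all(s.length >= 2 * printer.nozzle_diameter for s in layer.segments)
        assert len(layer.segments) == 0

    def test_deposited_area_conservation(self, printer):
        """Total fiber footprint = in-plane solid fraction x region area."""
        vol = make_fixture("box", (20, 20, 10), 0.1)
        pat = PorePattern(0.5, 1)
        layer = slice_layer(vol, PatternMap({1: pat}), 0, printer)
        deposited = sum(s.length * s.width for s in layer.segments)
        solid_fraction = pat.strut_width / pat.in_plane_period
        assert deposited == pytest.approx(solid_fraction * 400.0, rel=1e-9)


class TestSupport:
    def test_bed_resting_box_needs_none(self):
        vol = make_fixture("box", (10, 10, 5), 0.5)
        out = generate_support(vol)
        assert int((out.labels == SUPPORT_LABEL).sum()) == 0

    def test_floating_box_gap_filled_exactly(self):
        vol = make_fixture("floating_box", (10, 10, 5), 0.5, gap=2.0)
        out = generate_support(vol)
        n_support = int((out.labels == SUPPORT_LABEL).sum())
        assert n_support == 20 * 20 * 4  # footprint x 2 mm of voxels
        assert out.origin[2] == pytest.approx(0.0)

    def test_support_columns_are_contiguous_to_occupied(self):
        """Below the topmost occupied voxel of any column there is no void."""
        vol = make_fixture("blob", (12, 12, 10), 0.4, seed=5)
        out = generate_support(vol)
        occ = out.occupied
        for i, j in zip(*np.nonzero(occ.any(axis=2))):
            column = occ[i, j]
            top = np.nonzero(column)[0].max()
            assert column[: top + 1].all()

    def test_support_preserves_model_labels(self):
        vol = make_fixture("floating_box", (5, 5, 2), 0.5, gap=1.0)
        out = generate_support(vol)
        assert int((out.labels == 1).sum()) == int(vol.occupied.sum())


class TestSliceVolume:
    def test_layer_count_for_box(self, printer):
        vol = make_fixture("box", (20, 20, 10), 0.1)
        layers = slice_volume(vol, PatternMap({1: PorePattern(0.5, 1)}), printer)
        assert len(layers) == 50  # 10 mm / 0.2 mm
        assert all(b.z > a.z for a, b in zip(layers, layers[1:]))

    def test_stacked_layer_periodicity(self, printer):
        """Layers in the same orientation block repeat the same fibers."""
        vol = make_fixture("box", (10, 10, 4), 0.1)
        layers = slice_volume(vol, PatternMap({1: PorePattern(0.5, 3)}), printer)
        by_index = {l.layer_index: l for l in layers}
        # pore 0.5 -> 3-layer blocks; layers 0..2 identical in plan view
        for a, b in ((0, 1), (1, 2), (0, 12)):  # 12 = same parity block
            pa = [(s.start, s.end) for s in by_index[a].segments]
            pb = [(s.start, s.end) for s in by_index[b].segments]
            assert pa == pb

    def test_incompatible_pitch_rejected(self, printer):
        vol = make_fixture("box", (5, 5, 2), 0.3)
        with pytest.raises(ValueError, match="divide"):
            slice_volume(vol, PatternMap({1: PorePattern(0.5, 1)}), printer)

    def test_missing_pattern_names_label(self, printer):
        vol = label_linear_gradient(make_fixture("box", (5, 5, 2), 0.1), "x", 2)
        with pytest.raises(ValueError, match=r"\[2\]"):
            slice_volume(vol, PatternMap({1: PorePattern(0.5, 1)}), printer)

    def test_hybrid_segments_stay_near_their_region(self, printer):
        """Split box: both regions print on every layer and no fiber crosses
        the boundary by more than one nozzle width."""
        vol = label_linear_gradient(make_fixture("box", (20, 20, 10), 0.1), "x", 2)
        pm = PatternMap({1: PorePattern(0.5, 3), 2: PorePattern(0.8, 4)})
        layers = slice_volume(vol, pm, printer)
        w = printer.nozzle_diameter
        for layer in layers:
            regions = {s.region for s in layer.segments}
            assert regions == {1, 2}
            for s in layer.segments:
                xs = (s.start[0], s.end[0])
                ys = (s.start[1], s.end[1])
                if s.region == 1:
                    assert max(xs) <= 10.0 + w
                else:
                    assert min(xs) >= 10.0 - w
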