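"""Measurement pipeline: projection, segmentation, genotype, ROIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from poldep.design import GroundTruthEffect
from poldep.quantify import (AMBIGUOUS, FieldRejectedError, MeasurementError,
                             estimate_background, match_to_annotations,
                             max_project, measure_cell,
                             measurements_to_frame, quantify_field,
                             roi_radius_px, segment_cells)
from poldep.synthgen import DELETION, FieldParams, render_field

FP = FieldParams(shape=(320, 320), pixel_size_xy=0.2)
PS = FP.pixel_size_xy


def _pole_errors(stack, measurements):
    """Distances (um) between measured and annotated pole positions."""
    df = measurements_to_frame(measurements)
    m = match_to_annotations(df, stack.annotation_frame(), PS)
    d1 = np.hypot(m["end1_col"] * PS + PS / 2 - m["pole1_x"],
                  m["end1_row"] * PS + PS / 2 - m["pole1_y"])
    d2 = np.hypot(m["end2_col"] * PS + PS / 2 - m["pole2_x"],
                  m["end2_row"] * PS + PS / 2 - m["pole2_y"])
    return np.concatenate([d1, d2])


class TestMaxProject:
    def test_single_slice_identity(self):
        img = np.arange(12.0).reshape(1, 3, 4)
        np.testing.assert_array_equal(max_project(img), img[0])

    def test_all_zero(self):
        assert max_project(np.zeros((5, 4, 4))).sum() == 0

    def test_matches_brute_force_loop(self, rng):
        stack = rng.gamma(2.0, 50.0, size=(31, 24, 30))
        expected = stack[0].copy()
        for z in range(1, 31):
            expected = np.maximum(expected, stack[z])
        np.testing.assert_array_equal(max_project(stack), expected)

    @settings(deadline=None, max_examples=25)
    @given(hnp.arrays(np.float32, hnp.array_shapes(min_dims=3, max_dims=3,
                                                   min_side=1, max_side=8),
                      elements=st.floats(0, 1e4, width=32)))
    def test_projection_bounds_any_stack(self, stack):
        proj = max_project(stack)
        assert proj.shape == stack.shape[1:]
        assert (proj == stack.max(axis=0)).all()

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.zeros((0, 4, 4)))
        with pytest.raises(ValueError):
            max_project(np.zeros((4, 4)))


class TestSegmentation:
    def test_recovers_well_separated_cells_and_poles(self):
        stack = render_field("Tea1", "tea2", 3, 2, params=FP, seed=8)
        cells = segment_cells(max_project(stack, "gfp"), PS)
        assert len(cells) == 5
        assert all(c.ok for c in cells)
        fq = quantify_field(stack)
        errs = _pole_errors(stack, fq.measurements)
        assert len(errs) == 10
        assert errs.max() < 0.5  # um

    def test_empty_field_gives_empty_list(self):
        proj = np.full((128, 128), 100.0)
        assert segment_cells(proj, PS) == []

    def test_border_touching_cell_flagged(self):
        stack = render_field("Tea1", "tea2", 2, 2, params=FP, seed=8)
        proj = max_project(stack, "gfp")
        # crop through an interior cell so its mask hits the new border
        cell = stack.annotations[0].geometry
        col = int(cell.center[0] / PS)
        cropped = proj[:, col:]
        cells = segment_cells(cropped, PS)
        assert any("border" in c.qc_flags for c in cells)

    def test_mask_invariants(self):
        stack = render_field("Tea1", "tea2", 4, 4, params=FP, seed=15)
        for c in segment_cells(max_project(stack, "gfp"), PS):
            assert c.length_um >= c.width_um


class TestGenotype:
    def test_construction_calls(self, small_null_field):
        fq = quantify_field(small_null_field)
        df = measurements_to_frame(fq.measurements)
        m = match_to_annotations(df, small_null_field.annotation_frame(), PS)
        assert (m["genotype"] == m["genotype_true"]).all()

    def test_monte_carlo_accuracy_above_99_percent(self):
        total = correct = ambiguous = 0
        for seed in range(63):  # ~1000 cells
            stack = render_field("Tea1", "tea2", 8, 8, params=FP,
                                 seed=1000 + seed)
            fq = quantify_field(stack)
            df = measurements_to_frame(fq.measurements)
            m = match_to_annotations(df, stack.annotation_frame(), PS)
            total += len(stack.annotations)
            correct += int((m["genotype"] == m["genotype_true"]).sum())
            ambiguous += sum(1 for c in fq.cells
                             if c.genotype == AMBIGUOUS)
        assert total >= 1000
        assert correct / total >= 0.99
        assert ambiguous / total <= 0.01


class TestBackground:
    def test_constant_background_recovered_exactly(self):
        proj = np.full((200, 200), 37.5)
        assert estimate_background(proj, [], PS) == pytest.approx(37.5)

    def test_debris_region_avoided(self):
        proj = np.full((200, 200), 50.0)
        proj[40:44, 40:44] = 5000.0  # bright debris in one quadrant
        bg = estimate_background(proj, [], PS)
        assert bg == pytest.approx(50.0)

    def test_deterministic(self, small_null_field):
        proj = max_project(small_null_field, "gfp")
        cells = segment_cells(proj, PS)
        assert estimate_background(proj, cells, PS) == \
            estimate_background(proj, cells, PS)

    def test_field_without_free_space_rejected(self):
        proj = np.full((40, 40), 10.0)
        masks = np.ones((40, 40), dtype=bool)
        with pytest.raises(FieldRejectedError):
            estimate_background(proj, masks, PS)


class TestMeasureCell:
    def _uniform_cell(self, value=80.0, shape=(200, 200)):
        proj = np.full(shape, value)
        stack = render_field("Tea1", "tea2", 1, 1,
                             params=FieldParams(shape=shape,
                                                pixel_size_xy=PS),
                             seed=2)
        cells = segment_cells(max_project(stack, "gfp"), PS)
        return proj, cells[0]

    def test_background_identity_on_uniform_image(self):
        proj, cell = self._uniform_cell(80.0)
        m = measure_cell(cell, proj, background_mean=80.0, pixel_size=PS)
        for v in (m.end1_mean, m.end2_mean, m.cyto_mean,
                  m.end1_max, m.end2_max, m.cyto_max):
            assert v == 0.0

    def test_end_assignment_is_intensity_not_order_based(self):
        stack = render_field("Tea1", "tea2", 2, 2, params=FP, seed=30)
        proj = max_project(stack, "gfp")
        cells = segment_cells(proj, PS)
        bg = estimate_background(proj, cells, PS)
        cell = cells[0]
        a = measure_cell(cell, proj, bg, PS)
        cell.pole1, cell.pole2 = cell.pole2, cell.pole1
        b = measure_cell(cell, proj, bg, PS)
        assert a.end1_mean == b.end1_mean
        assert a.end2_mean == b.end2_mean

    def test_end1_is_the_rendered_brighter_pole(self):
        # over many cells the 2:1 brighter rendered tip must be called End1
        agree = total = 0
        for seed in range(6):
            stack = render_field("Tea1", "tea2", 6, 6, params=FP,
                                 seed=500 + seed)
            fq = quantify_field(stack)
            df = measurements_to_frame(fq.measurements)
            m = match_to_annotations(df, stack.annotation_frame(), PS)
            # annotation pole1 is the brighter rendered pole
            d = np.hypot(m["end1_col"] * PS + PS / 2 - m["pole1_x"],
                         m["end1_row"] * PS + PS / 2 - m["pole1_y"])
            # distinct tips only: ratio away from 1 by > noise
            distinct = m["true_end2"] / m["true_end1"] < 0.85
            agree += int((d[distinct] < 1.5).sum())
            total += int(distinct.sum())
        assert total > 40
        assert agree / total >= 0.95

    def test_disc_outside_image_raises(self):
        proj, cell = self._uniform_cell()
        cell.pole1 = (-50.0, -50.0)
        with pytest.raises(MeasurementError):
            measure_cell(cell, proj, 0.0, PS)

    def test_roi_radius_rounding(self):
        assert roi_radius_px(0.1) == 15
        assert roi_radius_px(0.2) == 8
        assert roi_radius_px(0.13) == 12


class TestFieldQuantification:
    def test_end_ordering_invariant(self, small_null_field):
        fq = quantify_field(small_null_field)
        for m in fq.measurements:
            assert m.end1_mean >= m.end2_mean

    def test_bookkeeping_segmented_equals_analysed_plus_excluded(
            self, small_null_field):
        fq = quantify_field(small_null_field)
        assert fq.n_segmented == fq.n_analysed + fq.n_excluded
        flagged = [c for c in fq.cells if not c.ok]
        assert len(flagged) == fq.n_excluded
        assert all(c.qc_flags for c in flagged)

    def test_corrected_end1_tracks_ground_truth(self):
        # recovery: r >= 0.9 between measured End1 and true tip amplitude
        frames, anns = [], []
        for seed in range(13):  # > 200 cells
            stack = render_field("Tea1", "tea2", 8, 8, params=FP,
                                 seed=700 + seed)
            fq = quantify_field(stack)
            frames.append(measurements_to_frame(fq.measurements))
            anns.append(stack.annotation_frame())
        df = pd.concat(frames, ignore_index=True)
        ann = pd.concat(anns, ignore_index=True)
        m = match_to_annotations(df, ann, PS)
        assert len(m) >= 200
        r = np.corrcoef(m["end1_mean"], m["true_end1"])[0, 1]
        assert r >= 0.9

    def test_end1_signal_monotone_in_multiplier(self):
        # expected measured End1 strictly increases across 3 levels
        means = []
        for mult in (0.6, 1.0, 1.5):
            eff = GroundTruthEffect("Tea1", "tea2",
                                    mult_end1=mult, mult_end2=mult)
            vals = []
            for seed in range(2):  # 2 x 16 deletion cells per level
                stack = render_field("Tea1", "tea2", 4, 16, truth=eff,
                                     params=FP, seed=77 + seed)
                fq = quantify_field(stack)
                vals += [m.end1_mean for m in fq.measurements
                         if m.genotype == DELETION]
            assert len(vals) >= 30
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
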