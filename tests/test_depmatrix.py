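"""Internal-control normalisation, matrix calls, NETO shift tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from poldep.depmatrix import (DECREASE, INCREASE, NS, MatrixCell,
                              MatrixIntegrityError, MissingArmError,
                              build_matrix, matrix_pivot, neto_shift_test,
                              normalize_to_controls, summarize_combination)
from poldep.design import GroundTruthEffect
from poldep.quantify import measurements_to_frame, quantify_field
from poldep.synthgen import FieldParams, render_field

FP = FieldParams(shape=(320, 320), pixel_size_xy=0.2)


def _toy_cells(rows):
    """Minimal measurement table from (field, genotype, e1, e2, cy)."""
    recs = []
    for i, (fid, gt, e1, e2, cy) in enumerate(rows):
        recs.append({
            "field_id": fid, "cell_id": f"c{i}", "marker": "Tea1",
            "deletion": "tea2", "genotype": gt,
            "end1_mean": e1, "end2_mean": e2, "cyto_mean": cy,
            "end1_max": e1, "end2_max": e2, "cyto_max": cy,
            "bipolarity_index": min(e2 / e1, 1.0) if e1 > 0 else 0.0,
        })
    return pd.DataFrame(recs)


class TestNormalization:
    def test_deletion_cell_equal_to_control_mean_normalizes_to_one(self):
        df = _toy_cells([("f0", "control", 10, 5, 2),
                         ("f0", "control", 30, 15, 6),
                         ("f0", "deletion", 20, 10, 4)])
        norm = normalize_to_controls(df)
        d = norm[norm.genotype == "deletion"].iloc[0]
        assert d["norm_end1"] == d["norm_end2"] == d["norm_cyto"] == 1.0

    def test_field_effects_cancel(self):
        # control means 10 and 20 in two fields; deletion values 5 and 10
        # both normalise to 0.5 — the whole point of the internal control
        df = _toy_cells([("f0", "control", 10, 10, 10),
                         ("f0", "deletion", 5, 5, 5),
                         ("f1", "control", 20, 20, 20),
                         ("f1", "deletion", 10, 10, 10)])
        norm = normalize_to_controls(df)
        dels = norm[norm.genotype == "deletion"]
        assert (dels["norm_end1"] == 0.5).all()

    def test_control_normalized_mean_is_one_per_field(self, null_pool):
        norm = null_pool["normalized"]
        g = (norm[norm.genotype == "control"]
             .groupby("field_id")[["norm_end1", "norm_end2", "norm_cyto"]]
             .mean())
        assert np.allclose(g.to_numpy(), 1.0, atol=1e-12)

    def test_null_truth_grand_mean_near_one(self, null_pool):
        # unbiasedness of the internal control: the deletion arm's grand
        # normalised mean sits at 1 up to its own sampling error (the
        # per-field control mean is an 8-cell estimate, so the grand
        # mean carries a field-level SE; 0.02 is kept as the floor)
        norm = null_pool["normalized"]
        dels = norm[norm.genotype == "deletion"]
        for col in ("norm_end1", "norm_end2", "norm_cyto"):
            per_field = dels.groupby("field_id")[col].mean()
            se = per_field.std() / np.sqrt(len(per_field))
            assert abs(dels[col].mean() - 1.0) < max(0.02, 3 * se)

    def test_field_without_controls_dropped_with_warning(self, caplog):
        df = _toy_cells([("f0", "control", 10, 5, 2),
                         ("f0", "deletion", 5, 2, 1),
                         ("f1", "deletion", 7, 3, 2)])
        with caplog.at_level("WARNING"):
            norm = normalize_to_controls(df)
        assert set(norm["field_id"]) == {"f0"}
        assert "no control cells" in caplog.text

    def test_nonpositive_control_mean_rejects_field(self, caplog):
        df = _toy_cells([("f0", "control", 10, 5, 2)])
        df.loc[0, "cyto_mean"] = -1.0
        with caplog.at_level("WARNING"):
            norm = normalize_to_controls(df)
        assert norm.empty


class TestSummarize:
    def test_identical_arms_not_significant(self, null_pool):
        # repeated null sub-studies: 10 draws, at most 1 expected p < 0.05
        norm = null_pool["normalized"]
        rng = np.random.default_rng(17)
        sig = 0
        for _ in range(10):
            d = norm[norm.genotype == "deletion"].sample(
                50, random_state=rng.integers(2 ** 31))
            c = norm[norm.genotype == "control"].sample(
                50, random_state=rng.integers(2 ** 31))
            mc = summarize_combination(pd.concat([d, c]), "end1",
                                       min_cells=50)
            assert abs(mc.rel_diff) < 0.15
            sig += mc.p_value < 0.05
        assert sig <= 2

    def test_half_multiplier_recovered(self, half_end_study):
        norm, _ = half_end_study
        mc = summarize_combination(norm, "end1", min_cells=100)
        assert -0.6 <= mc.rel_diff <= -0.4
        assert mc.p_value < 1e-3
        assert not mc.underpowered

    def test_type_one_error_calibrated(self, null_pool):
        # long-run false-positive rate of the Welch-on-log test at
        # alpha = 0.05 over 400 sub-sampled null comparisons
        norm = null_pool["normalized"]
        dels = norm[norm.genotype == "deletion"]
        ctrls = norm[norm.genotype == "control"]
        rng = np.random.default_rng(99)
        hits = trials = 0
        for _ in range(134):
            sub = pd.concat([
                dels.sample(30, random_state=rng.integers(2 ** 31)),
                ctrls.sample(30, random_state=rng.integers(2 ** 31))])
            for comp in ("end1", "end2", "cyto"):
                p = summarize_combination(sub, comp, min_cells=30).p_value
                hits += p < 0.05
                trials += 1
        assert trials >= 400
        assert abs(hits / trials - 0.05) <= 0.02

    def test_empty_arm_raises(self):
        df = _toy_cells([("f0", "control", 10, 5, 2)])
        norm = normalize_to_controls(df)
        with pytest.raises(MissingArmError):
            summarize_combination(norm, "end1")

    def test_underpowered_flagged_not_dropped(self):
        df = _toy_cells([("f0", "control", 10, 5, 2),
                         ("f0", "control", 12, 6, 2),
                         ("f0", "deletion", 11, 5, 2),
                         ("f0", "deletion", 9, 4, 2)])
        mc = summarize_combination(normalize_to_controls(df), "end1",
                                   min_cells=100)
        assert mc.underpowered
        assert mc.n_del == 2 and mc.n_ctrl == 2


class TestBuildMatrix:
    def _entries(self, n=6, p=1.0, rel=0.0):
        return [MatrixCell("Tea1", f"d{i}", "end1", 100, 100, rel, p)
                for i in range(n)]

    def test_all_p_one_gives_all_ns(self):
        mat = build_matrix(self._entries(p=1.0, rel=0.5))
        assert (mat["call"] == NS).all()

    def test_call_requires_both_q_and_effect_size(self):
        entries = [
            MatrixCell("Tea1", "d1", "end1", 100, 100, 0.50, 1e-8),
            MatrixCell("Tea1", "d2", "end1", 100, 100, 0.05, 1e-8),
            MatrixCell("Tea1", "d3", "end1", 100, 100, -0.50, 1e-8),
            MatrixCell("Tea1", "d4", "end1", 100, 100, 0.50, 0.9),
        ]
        mat = build_matrix(entries, alpha=0.05, min_effect=0.10)
        calls = dict(zip(mat["deletion"], mat["call"]))
        assert calls == {"d1": INCREASE, "d2": NS, "d3": DECREASE,
                         "d4": NS}

    def test_duplicate_entries_rejected(self):
        e = self._entries(2)
        with pytest.raises(MatrixIntegrityError):
            build_matrix(e + [e[0]])

    def test_pivot_shape_default_design(self):
        entries = []
        markers = [f"M{i}" for i in range(9)]
        deletions = [f"d{j}" for j in range(10)]
        for m in markers:
            for d in deletions:
                for comp in ("end1", "end2", "cyto"):
                    entries.append(MatrixCell(m, d, comp, 100, 100, 0.0,
                                              0.5))
        mat = build_matrix(entries)
        wide = matrix_pivot(mat, "end1")
        assert wide.shape == (9, 10)


class TestNeto:
    def test_planted_bipolarity_shift_detected(self):
        eff = GroundTruthEffect("For3", "tea1", bipolarity_shift=-0.25)
        frames = []
        for seed in range(9):
            stack = render_field("For3", "tea1", 8, 8, truth=eff,
                                 params=FP, seed=40 + seed,
                                 field_id=f"f{seed}")
            fq = quantify_field(stack)
            frames.append(measurements_to_frame(fq.measurements))
        norm = normalize_to_controls(pd.concat(frames, ignore_index=True))
        neto = neto_shift_test(norm)
        row = neto.iloc[0]
        assert row["delta_bipolarity"] < 0
        assert row["shifted"]

    def test_null_shift_rarely_called(self, null_pool):
        norm = null_pool["normalized"]
        dels = norm[norm.genotype == "deletion"]
        ctrls = norm[norm.genotype == "control"]
        rng = np.random.default_rng(7)
        frames = []
        for rep in range(50):
            sub = pd.concat([
                dels.sample(100, random_state=rng.integers(2 ** 31)),
                ctrls.sample(100, random_state=rng.integers(2 ** 31))])
            sub = sub.copy()
            sub["deletion"] = f"rep{rep}"
            frames.append(sub)
        neto = neto_shift_test(pd.concat(frames, ignore_index=True))
        assert (~neto["shifted"]).mean() >= 0.90

    def test_all_monopolar_cells_give_zero_delta(self):
        # bipolarity index 0 in both arms (the shift test reads the
        # per-cell index directly, no intensity normalisation involved)
        df = _toy_cells([("f0", "control", 10, 0, 2)] * 5
                        + [("f0", "deletion", 10, 0, 2)] * 5)
        neto = neto_shift_test(df)
        assert neto.iloc[0]["delta_bipolarity"] == 0.0
        assert not neto.iloc[0]["shifted"]


class TestScaleInvariance:
    def test_constant_intensity_scaling_changes_nothing(self):
        # the internal-control property: a x2 gain change on one field
        # must leave normalised values, rel_diff and p identical
        stacks = [render_field("Tea1", "tea2", 6, 6, params=FP, seed=s,
                               field_id=f"f{s}") for s in (61, 62)]
        def run(scale_field0):
            frames = []
            for i, st in enumerate(stacks):
                st2 = dataclasses.replace(
                    st, gfp=st.gfp * (2.0 if (i == 0 and scale_field0)
                                      else 1.0),
                    red=st.red * (2.0 if (i == 0 and scale_field0)
                                  else 1.0),
                    annotations=st.annotations)
                fq = quantify_field(st2)
                frames.append(measurements_to_frame(fq.measurements))
            norm = normalize_to_controls(
                pd.concat(frames, ignore_index=True))
            mc = summarize_combination(norm, "end1", min_cells=6)
            return norm, mc
        norm_a, mc_a = run(False)
        norm_b, mc_b = run(True)
        assert len(norm_a) == len(norm_b)
        for col in ("norm_end1", "norm_end2", "norm_cyto"):
            np.testing.assert_allclose(norm_a[col], norm_b[col],
                                       rtol=1e-9, atol=1e-12)
        assert mc_a.rel_diff == pytest.approx(mc_b.rel_diff, abs=1e-9)
        assert mc_a.p_value == pytest.approx(mc_b.p_value, abs=1e-9)
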