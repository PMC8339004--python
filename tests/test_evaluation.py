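import math

import numpy as np
import pandas as pd
import pytest

from cxrsim import (
    Mark,
    MatchedRatings,
    ValidationError,
    combine_detections,
    compute_froc,
    compute_wafroc,
    lesion_weights,
    load_rating_table,
    marks_from_segmentation,
    match_marks,
    summarize_counts,
    wafroc_curve_area,
    wllf_at,
)
from cxrsim.evaluation import UNMARKED, write_rating_table


def make_ratings(lesions, fps, healthy):
    """Build MatchedRatings directly.

    lesions: {case: [scores or None]}, fps: {case: [scores]}, healthy: [case].
    """
    r = MatchedRatings(healthy_cases=list(healthy), diseased_cases=list(lesions))
    for case, scores in lesions.items():
        w = 1.0 / len(scores)
        for lid, s in enumerate(scores, start=1):
            r.lesion_ratings[(case, lid)] = UNMARKED if s is None else float(s)
            r.lesion_weights[(case, lid)] = w
    for case in list(lesions) + list(healthy):
        r.nl_scores[case] = [float(s) for s in fps.get(case, [])]
    return r


def brute_force_fom(ratings):
    """Direct psi-kernel evaluation, independent of the implementation."""
    def psi(a, b):
        return 1.0 if b > a else (0.5 if b == a else 0.0)

    fp = ratings.fp_per_healthy_case()
    total = 0.0
    for a in fp.values():
        for key, z in ratings.lesion_ratings.items():
            total += ratings.lesion_weights[key] * psi(a, z)
    return total / (ratings.K_N * ratings.K_F)


def random_instance(rng):
    """A random small study: <= 6 cases, integer scores to force ties."""
    n_dis = int(rng.integers(1, 4))
    n_heal = int(rng.integers(1, 4))
    lesions = {}
    fps = {}
    for k in range(n_dis):
        case = f"d{k}"
        n_l = int(rng.integers(1, 4))
        lesions[case] = [
            None if rng.random() < 0.3 else int(rng.integers(0, 4)) for _ in range(n_l)
        ]
        fps[case] = [int(s) for s in rng.integers(0, 4, size=rng.integers(0, 3))]
    healthy = [f"h{k}" for k in range(n_heal)]
    for case in healthy:
        fps[case] = [int(s) for s in rng.integers(0, 4, size=rng.integers(0, 3))]
    return make_ratings(lesions, fps, healthy)


class TestMatchMarks:
    @pytest.fixture()
    def manifest_lesions(self):
        return pd.DataFrame(
            dict(case_id=["c1", "c1"], lesion_id=[1, 2],
                 com_x=[100.0, 300.0], com_y=[100.0, 300.0],
                 weight=[0.5, 0.5])
        )

    def test_distance_just_below_radius_is_a_hit(self, manifest_lesions):
        marks = [Mark("c1", 100.0 + 29.9, 100.0, 0.8)]
        r = match_marks(marks, manifest_lesions, radius_px=30)
        assert r.lesion_ratings[("c1", 1)] == 0.8
        assert r.nl_scores["c1"] == []

    def test_distance_exactly_at_radius_is_a_miss(self, manifest_lesions):
        marks = [Mark("c1", 130.0, 100.0, 0.8)]
        r = match_marks(marks, manifest_lesions, radius_px=30)
        assert r.lesion_ratings[("c1", 1)] == UNMARKED
        assert r.nl_scores["c1"] == [0.8]

    def test_inclusive_radius_option(self, manifest_lesions):
        marks = [Mark("c1", 130.0, 100.0, 0.8)]
        r = match_marks(marks, manifest_lesions, radius_px=30, inclusive_radius=True)
        assert r.lesion_ratings[("c1", 1)] == 0.8

    def test_equal_scores_resolved_by_distance(self, manifest_lesions):
        near = Mark("c1", 105.0, 100.0, 0.5)
        far = Mark("c1", 110.0, 100.0, 0.5)
        for order in ([near, far], [far, near]):  # brute force both input orders
            r = match_marks(order, manifest_lesions)
            assert r.lesion_ratings[("c1", 1)] == 0.5
            assert r.nl_scores["c1"] == [0.5]

    def test_higher_score_wins_one_to_one(self, manifest_lesions):
        marks = [Mark("c1", 101.0, 100.0, 0.9), Mark("c1", 102.0, 100.0, 0.7)]
        r = match_marks(marks, manifest_lesions)
        assert r.lesion_ratings[("c1", 1)] == 0.9
        assert r.nl_scores["c1"] == [0.7]

    def test_every_mark_classified_once(self, manifest_lesions, rng):
        marks = [
            Mark("c1", float(x), float(y), float(s))
            for x, y, s in zip(rng.uniform(0, 400, 25), rng.uniform(0, 400, 25),
                               rng.random(25))
        ]
        r = match_marks(marks, manifest_lesions)
        n_ll = sum(1 for z in r.lesion_ratings.values() if np.isfinite(z))
        n_nl = sum(len(v) for v in r.nl_scores.values())
        assert n_ll + n_nl == 25

    def test_unknown_case_rejected(self, manifest_lesions):
        with pytest.raises(ValidationError):
            match_marks([Mark("zz", 0, 0, 1.0)], manifest_lesions)

    def test_duplicate_marks_collapsed_with_warning(self, manifest_lesions):
        marks = [Mark("c1", 500.0, 100.0, 0.8)] * 2
        with pytest.warns(UserWarning, match="duplicate"):
            r = match_marks(marks, manifest_lesions)
        assert r.nl_scores["c1"] == [0.8]

    def test_score_threshold_discards_low_marks(self, manifest_lesions):
        marks = [Mark("c1", 100.0, 100.0, 0.2)]
        r = match_marks(marks, manifest_lesions, score_threshold=0.5)
        assert r.lesion_ratings[("c1", 1)] == UNMARKED


class TestLesionWeights:
    def test_four_lesions_quarter_each(self):
        assert lesion_weights(4) == [0.25] * 4

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 7])
    def test_sum_to_unity(self, n):
        w = lesion_weights(n)
        assert len(w) == n
        assert abs(sum(w) - 1.0) < 1e-12

    def test_invalid_count_rejected(self):
        with pytest.raises(ValidationError):
            lesion_weights(0)


class TestFROC:
    def test_perfect_detector(self):
        r = make_ratings({"d1": [1.0, 1.0]}, {}, ["h1"])
        c = compute_froc(r)
        i = np.searchsorted(-c.thresholds, -0.5, side="left") - 1
        assert c.llf[i] == 1.0 and c.nlf[i] == 0.0

    def test_no_marks_degenerates_to_origin(self):
        r = make_ratings({"d1": [None]}, {}, ["h1"])
        c = compute_froc(r)
        assert c.llf.tolist() == [0.0] and c.nlf.tolist() == [0.0]

    def test_counts_from_definition(self):
        # one case with 2 lesions marked 0.9/0.4; one healthy case with FP 0.6
        r = make_ratings({"d1": [0.9, 0.4]}, {"h1": [0.6]}, ["h1"])
        c = compute_froc(r)
        at = {z: (l, n) for z, l, n in zip(c.thresholds, c.llf, c.nlf)}
        assert at[0.6] == (0.5, 0.5)  # zeta=0.5 operating point sits between 0.6 and 0.4
        assert at[0.9] == (0.5, 0.0)
        assert at[0.4] == (1.0, 0.5)

    def test_llf_monotone_nondecreasing(self, rng):
        for _ in range(20):
            r = random_instance(rng)
            try:
                c = compute_froc(r)
            except ValidationError:
                continue
            assert np.all(np.diff(c.llf) >= 0) and np.all(np.diff(c.nlf) >= 0)


class TestWAFROC:
    def test_perfect_separation_gives_fom_one(self):
        r = make_ratings({"d1": [0.9], "d2": [0.8, 0.8]}, {"h1": [0.1], "h2": []},
                         ["h1", "h2"])
        assert compute_wafroc(r).fom == 1.0

    def test_no_marks_anywhere_gives_half(self):
        r = make_ratings({"d1": [None]}, {}, ["h1"])
        assert compute_wafroc(r).fom == 0.5

    def test_fom_equals_brute_force_psi(self, rng):
        for _ in range(50):
            r = random_instance(rng)
            assert compute_wafroc(r).fom == pytest.approx(brute_force_fom(r), abs=1e-12)

    def test_fom_equals_trapezoidal_curve_area(self, rng):
        """Psi-kernel FOM == area under the extended empirical wAFROC curve."""
        for _ in range(120):
            r = random_instance(rng)
            res = compute_wafroc(r)
            assert res.fom == pytest.approx(wafroc_curve_area(res), abs=1e-12)

    def test_fom_invariant_under_monotone_transform(self, rng):
        for _ in range(10):
            r = random_instance(rng)
            base = compute_wafroc(r).fom
            t = MatchedRatings(
                lesion_ratings={
                    k: (math.exp(v) if np.isfinite(v) else v)
                    for k, v in r.lesion_ratings.items()
                },
                lesion_weights=dict(r.lesion_weights),
                nl_scores={k: [math.exp(s) for s in v] for k, v in r.nl_scores.items()},
                healthy_cases=r.healthy_cases,
                diseased_cases=r.diseased_cases,
            )
            assert compute_wafroc(t).fom == pytest.approx(base, abs=1e-12)

    def test_wllf_equals_llf_for_equal_lesion_counts(self, rng):
        r = make_ratings({"d1": [0.9, None], "d2": [0.7, 0.3]}, {"h1": [0.5]}, ["h1"])
        froc = compute_froc(r)
        wa = compute_wafroc(r)
        np.testing.assert_allclose(wa.wllf, froc.llf)

    def test_requires_healthy_cases(self):
        r = make_ratings({"d1": [0.9]}, {}, [])
        with pytest.raises(ValidationError, match="nodule-free"):
            compute_wafroc(r)


class TestWllfAt:
    def test_origin(self):
        r = make_ratings({"d1": [0.9]}, {"h1": [0.5]}, ["h1"])
        assert wllf_at(compute_wafroc(r), 0.0) == 1.0  # point (0, 1) observed at zeta=0.9

    def test_exact_observed_point(self):
        r = make_ratings({"d1": [0.4]}, {"h1": [0.6]}, ["h1", "h2"])
        res = compute_wafroc(r)
        # at zeta=0.6: FPF=0.5, wLLF=0; at zeta=0.4: FPF=0.5, wLLF=1
        assert wllf_at(res, 0.5) == 1.0

    def test_interpolated_point_against_brute_force_tracing(self):
        # 5 cases: 3 diseased, 2 healthy
        r = make_ratings(
            {"d1": [0.9, 0.2], "d2": [0.7], "d3": [None, 0.5]},
            {"h1": [0.6], "h2": []},
            ["h1", "h2"],
        )
        res = compute_wafroc(r)
        # thresholds 0.9,.7,.6,.5,.4(none here),... tracing by hand:
        # zeta=0.9: FPF 0, wLLF 1/6; 0.7: 0, 1/2; 0.6: 1/2, 1/2; 0.5: 1/2, 2/3; 0.2: 1/2, 5/6
        # beyond: extension to (1,1). At FPF=0.2 interpolate 0->1/2 between wLLF 1/2... :
        # envelope x=0 -> max wLLF 1/2, x=1/2 -> 5/6 ; interp at 0.2 = 1/2 + (5/6-1/2)*0.4
        assert wllf_at(res, 0.2) == pytest.approx(0.5 + (5 / 6 - 0.5) * 0.4, abs=1e-12)

    def test_invalid_fpf_rejected(self):
        r = make_ratings({"d1": [0.9]}, {"h1": [0.5]}, ["h1"])
        with pytest.raises(ValidationError):
            wllf_at(compute_wafroc(r), 1.5)


class TestSummarizeCounts:
    def test_partition_tp_fn(self, rng):
        for _ in range(10):
            r = random_instance(rng)
            tp, fp, fn = summarize_counts(r, zeta=2)
            assert tp + fn == r.n_lesions

    def test_perfect_detector_has_no_fn(self):
        r = make_ratings({"d1": [0.9, 0.8]}, {}, ["h1"])
        assert summarize_counts(r, 0.5) == (2, 0, 0)

    def test_threshold_straddling_enumeration(self):
        r = make_ratings({"d1": [0.9, 0.5], "d2": [0.3]}, {"d1": [0.5], "h1": [0.2]},
                         ["h1"])
        assert summarize_counts(r, 0.5) == (2, 1, 1)          # >= zeta
        assert summarize_counts(r, 0.5, strict=True) == (1, 0, 2)  # > zeta


class TestCombineDetections:
    def test_mark_at_center_retains_box(self):
        boxes = [("c1", (10, 10, 30, 30), 0.7)]
        out = combine_detections(boxes, [Mark("c1", 20, 20, 1.0)])
        assert len(out) == 1 and out[0].x == 20 and out[0].score == 0.7

    def test_no_seg_marks_gives_empty(self):
        assert combine_detections([("c1", (0, 0, 5, 5), 0.5)], []) == []

    def test_mark_on_edge_is_inclusive(self):
        out = combine_detections([("c1", (10, 10, 30, 30), 0.7)], [Mark("c1", 30, 20, 1.0)])
        assert len(out) == 1

    def test_wrong_case_does_not_match(self):
        assert combine_detections([("c1", (0, 0, 5, 5), 0.5)], [Mark("c2", 2, 2, 1.0)]) == []

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValidationError):
            combine_detections([("c1", (10, 10, 10, 30), 0.7)], [])


class TestMarksFromSegmentation:
    def test_two_blobs_give_two_marks_at_coms(self):
        mask = np.zeros((50, 50), bool)
        mask[5:10, 5:10] = True
        mask[30:35, 40:45] = True
        marks = marks_from_segmentation(mask, case_id="c")
        assert len(marks) == 2
        assert sorted((m.x, m.y) for m in marks) == [(7.0, 7.0), (42.0, 32.0)]
        assert all(m.score == 1.0 for m in marks)

    def test_empty_mask_gives_empty_list(self):
        assert marks_from_segmentation(np.zeros((10, 10), bool)) == []

    def test_l_shaped_blob_com_matches_pixel_average(self):
        mask = np.zeros((20, 20), bool)
        mask[2:10, 2:4] = True
        mask[8:10, 2:12] = True
        (m,) = marks_from_segmentation(mask)
        ys, xs = np.nonzero(mask)
        assert m.x == pytest.approx(xs.mean()) and m.y == pytest.approx(ys.mean())

    def test_scores_from_score_image(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        scores = np.linspace(0, 1, 100).reshape(10, 10)
        (m,) = marks_from_segmentation(mask, scores)
        assert m.score == pytest.approx(scores[2:5, 2:5].max())


class TestRatingTables:
    def make_tables(self):
        truth = pd.DataFrame(
            dict(CaseID=["d1", "d1", "h1"], LesionID=[1, 2, 0], Weight=[0.5, 0.5, 0.0])
        )
        nl = pd.DataFrame(
            dict(ReaderID=["r1"], ModalityID=["m1"], CaseID=["h1"], NL_Rating=[40.0])
        )
        ll = pd.DataFrame(
            dict(ReaderID=["r1", "r1"], ModalityID=["m1", "m1"], CaseID=["d1", "d1"],
                 LesionID=[1, 2], LL_Rating=[90.0, 30.0])
        )
        return truth, nl, ll

    @pytest.mark.parametrize("fmt", ["dir", "xlsx"])
    def test_round_trip(self, tmp_path, fmt):
        truth, nl, ll = self.make_tables()
        path = tmp_path / ("tables.xlsx" if fmt == "xlsx" else "tables")
        write_rating_table(path, truth, nl, ll)
        ratings = load_rating_table(path)[("m1", "r1")]
        assert ratings.lesion_ratings[("d1", 1)] == 90.0
        assert ratings.lesion_ratings[("d1", 2)] == 30.0
        assert ratings.nl_scores["h1"] == [40.0]
        assert ratings.K_N == 1 and ratings.K_F == 1

    def test_bad_weight_sum_rejected(self, tmp_path):
        truth, nl, ll = self.make_tables()
        truth.loc[0, "Weight"] = 0.4  # sums to 0.9
        write_rating_table(tmp_path / "t", truth, nl, ll)
        with pytest.raises(ValidationError, match="sum"):
            load_rating_table(tmp_path / "t")

    def test_unknown_lesion_reference_rejected(self, tmp_path):
        truth, nl, ll = self.make_tables()
        ll.loc[0, "LesionID"] = 9
        write_rating_table(tmp_path / "t", truth, nl, ll)
        with pytest.raises(ValidationError, match="unknown lesion"):
            load_rating_table(tmp_path / "t")

    def test_fom_matches_hand_computed_wilcoxon(self, tmp_path):
        # 4 cases: d1 (2 lesions 90/30), d2 (1 lesion unmarked), h1 (FP 40), h2 (no mark)
        truth = pd.DataFrame(
            dict(CaseID=["d1", "d1", "d2", "h1", "h2"], LesionID=[1, 2, 1, 0, 0],
                 Weight=[0.5, 0.5, 1.0, 0.0, 0.0])
        )
        nl = pd.DataFrame(
            dict(ReaderID=["r1"], ModalityID=["m1"], CaseID=["h1"], NL_Rating=[40.0])
        )
        ll = pd.DataFrame(
            dict(ReaderID=["r1", "r1"], ModalityID=["m1", "m1"], CaseID=["d1", "d1"],
                 LesionID=[1, 2], LL_Rating=[90.0, 30.0])
        )
        write_rating_table(tmp_path / "t", truth, nl, ll)
        ratings = load_rating_table(tmp_path / "t")[("m1", "r1")]
        # psi kernel by hand over (healthy, lesion) pairs:
        # h1 (FP 40): 0.5*1 (90>40) + 0.5*0 (30<40) + 1.0*0 (unmarked) = 0.5
        # h2 (-inf): 0.5*1 + 0.5*1 + 1.0*0.5 (tie of two no-marks) = 1.5
        # FOM = (0.5 + 1.5) / (K_N=2 * K_F=2) = 0.5
        assert compute_wafroc(ratings).fom == pytest.approx(0.5, abs=1e-12)
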