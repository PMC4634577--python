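"""Classification protocols, performance measures and the MCC grid search."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catsim.evaluation import (
    Agreement,
    ConfusionCounts,
    EvaluationConfig,
    Mode,
    ScoredCandidate,
    best_hit,
    best_hit_evaluation,
    classify_best_hit,
    classify_thresholded,
    grid_search,
    ident_supfam,
    mcc,
    round_half_up,
    sensitivity,
)

from conftest import build_site


def _cand(target="T", score=0.5, same_sf=False, ec=True, s_go=None):
    return ScoredCandidate(target_id=target, score=score, same_superfamily=same_sf,
                           ec_class_match=ec, s_go=s_go)


class TestIdentSupfam:
    def test_equal_and_different_labels(self):
        a = build_site(["HIS", "ASP"], superfamily="c.1.8")
        b = build_site(["HIS", "ASP"], site_id="B", superfamily="c.1.8")
        c = build_site(["HIS", "ASP"], site_id="C", superfamily="b.2.4")
        assert ident_supfam(a, b) and not ident_supfam(a, c)

    def test_missing_label_is_an_error(self):
        a = build_site(["HIS", "ASP"], superfamily=None)
        b = build_site(["HIS", "ASP"], site_id="B")
        with pytest.raises(ValueError):
            ident_supfam(a, b)


class TestBestHit:
    def test_lowest_score_wins(self):
        cands = [_cand("a", 0.5), _cand("b", 0.2), _cand("c", 0.9)]
        hit = best_hit(cands, EvaluationConfig(mode=Mode.ALL))
        assert hit.target_id == "b"

    def test_best_of_k_takes_highest_sgo_among_k_best(self):
        cands = [_cand("a", 0.2, s_go=0.1), _cand("b", 0.25, s_go=0.9),
                 _cand("c", 0.9, s_go=1.0)]
        hit = best_hit(cands, EvaluationConfig(mode=Mode.ALL, k=2))
        assert hit.target_id == "b"

    def test_diff_sf_excludes_homologous_candidates(self):
        cands = [_cand("a", 0.1, same_sf=True), _cand("b", 0.7, same_sf=True)]
        assert best_hit(cands, EvaluationConfig(mode=Mode.DIFF_SF)) is None
        hit = best_hit(cands, EvaluationConfig(mode=Mode.ALL))
        assert hit.target_id == "a"


class TestClassification:
    def test_best_hit_protocol_uses_first_ec_digit(self):
        # EC 3.2.1.8 vs 3.1.3.48 share class 3 -> TP; class 1 vs 2 -> FN
        a = build_site(["HIS", "ASP"], ec="3.2.1.8")
        b = build_site(["HIS", "ASP"], site_id="B", ec="3.1.3.48")
        assert a.ec_class == b.ec_class == "3"
        assert classify_best_hit(_cand(ec=True)) == "TP"
        assert classify_best_hit(_cand(ec=False)) == "FN"

    @pytest.mark.parametrize("score,cu,agree,expected", [
        (0.50, 0.65, True, "TP"),
        (0.70, 0.65, True, "FN"),
        (0.50, 0.65, False, "FP"),
        (0.70, 0.65, False, "TN"),
        (0.65, 0.65, True, "FN"),   # boundary: score >= cutoff is negative
    ])
    def test_thresholded_protocol_ec_agreement(self, score, cu, agree, expected):
        hit = _cand(score=score, ec=agree)
        assert classify_thresholded(hit, cu, None, Agreement.EC_CLASS) == expected

    def test_thresholded_protocol_go_agreement(self):
        hit = _cand(score=0.50, s_go=0.80)
        assert classify_thresholded(hit, 0.65, 0.88, Agreement.GO) == "FP"
        assert classify_thresholded(hit, 0.65, 0.75, Agreement.GO) == "TP"

    def test_undefined_sgo_excludes_query_under_go_agreement(self):
        hit = _cand(score=0.50, s_go=None)
        assert classify_thresholded(hit, 0.65, 0.88, Agreement.GO) is None


class TestMeasures:
    @pytest.mark.parametrize("tp,fn,expected", [
        (167, 53, 0.76),   # best ALL-mode raw-RMSD row
        (0, 9, 0.0),
        (61, 159, 0.28),   # 61/220 = 0.2773
    ])
    def test_sensitivity(self, tp, fn, expected):
        value = sensitivity(ConfusionCounts(tp=tp, fp=0, tn=0, fn=fn))
        assert round_half_up(value) == expected

    def test_sensitivity_undefined_without_positives(self):
        assert sensitivity(ConfusionCounts(tp=0, fp=3, tn=5, fn=0)) is None

    @pytest.mark.parametrize("counts,expected", [
        ((61, 58, 417, 159), 0.19),
        ((5, 5, 607, 1), 0.64),
        ((1, 1, 1, 1), 0.0),
    ])
    def test_mcc_known_values(self, counts, expected):
        tp, fp, tn, fn = counts
        value = mcc(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert round_half_up(value) == expected

    def test_mcc_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=5, fp=0, tn=0, fn=0)) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_mcc_and_sensitivity_bounds(self, counts):
        c = ConfusionCounts(*counts)
        assert -1.0 <= mcc(c) <= 1.0
        s = sensitivity(c)
        if s is not None:
            assert 0.0 <= s <= 1.0


def _brute_force_grid(comparisons, config, rmsd_grid, sgo_grid):
    """Oracle: recompute counts/MCC at every grid point via the classify op."""
    best = None
    sgo_values = sgo_grid if config.agreement is Agreement.GO else [None]
    for cu_sgo in sgo_values:
        for cu_rmsd in rmsd_grid:
            counts = ConfusionCounts()
            for qid in sorted(comparisons):
                hit = best_hit(comparisons[qid], config)
                if hit is None:
                    continue
                outcome = classify_thresholded(hit, cu_rmsd, cu_sgo,
                                               config.agreement)
                if outcome is not None:
                    counts.add(outcome)
            val = mcc(counts)
            key = (-val, cu_rmsd, -(cu_sgo if cu_sgo is not None else 0.0))
            if best is None or key < best[0]:
                best = (key, cu_rmsd, cu_sgo, val, counts)
    return best


class TestGridSearch:
    def _separable(self):
        """Planted separation: agreeing hits score ~0.3, others ~0.8."""
        rng = np.random.default_rng(0)
        comps = {}
        for q in range(30):
            agree = q % 2 == 0
            score = (0.3 if agree else 0.8) + rng.uniform(-0.05, 0.05)
            comps[f"q{q}"] = [_cand("t", score, ec=agree, s_go=1.0 if agree else 0.2)]
        return comps

    def test_planted_separation_recovered_with_perfect_mcc(self):
        comps = self._separable()
        res = grid_search(comps, EvaluationConfig(mode=Mode.ALL,
                                                  agreement=Agreement.EC_CLASS))
        assert res.mcc == pytest.approx(1.0)
        assert 0.34 <= res.cu_rmsd <= 0.76  # any cutoff in the separation gap

    def test_single_grid_point_returned(self):
        comps = self._separable()
        res = grid_search(comps, EvaluationConfig(mode=Mode.ALL,
                                                  agreement=Agreement.EC_CLASS),
                          rmsd_grid=[0.5])
        assert res.cu_rmsd == 0.5

    @pytest.mark.parametrize("agreement", [Agreement.EC_CLASS, Agreement.GO])
    def test_equals_exhaustive_recomputation(self, agreement):
        rng = np.random.default_rng(1)
        comps = {}
        for q in range(25):
            cands = [_cand(f"t{j}", float(rng.uniform(0, 1.5)),
                           same_sf=bool(rng.random() < 0.3),
                           ec=bool(rng.random() < 0.5),
                           s_go=float(rng.uniform(0, 1)))
                     for j in range(4)]
            comps[f"q{q}"] = cands
        config = EvaluationConfig(mode=Mode.DIFF_SF, agreement=agreement)
        rmsd_grid = np.round(np.arange(1, 31) * 0.05, 2)
        sgo_grid = np.round(np.arange(10, 21) * 0.05, 2)
        res = grid_search(comps, config, rmsd_grid, sgo_grid)
        _, cu_rmsd, cu_sgo, val, counts = _brute_force_grid(
            comps, config, rmsd_grid, sgo_grid)
        assert res.mcc == pytest.approx(val, abs=1e-12)
        assert res.cu_rmsd == pytest.approx(cu_rmsd)
        if agreement is Agreement.GO:
            assert res.cu_sgo == pytest.approx(cu_sgo)
        assert (res.counts.tp, res.counts.fp, res.counts.tn, res.counts.fn) == \
            (counts.tp, counts.fp, counts.tn, counts.fn)

    def test_empty_grid_is_configuration_error(self):
        with pytest.raises(ValueError):
            grid_search(self._separable(),
                        EvaluationConfig(mode=Mode.ALL), rmsd_grid=[])


class TestBestHitEvaluation:
    def test_counts_conserved_and_dropped_reported(self):
        comps = {
            "q1": [_cand("a", 0.2, ec=True)],
            "q2": [_cand("b", 0.4, ec=False)],
            "q3": [_cand("c", 0.1, same_sf=True)],  # no admissible candidate
        }
        counts, dropped = best_hit_evaluation(
            comps, EvaluationConfig(mode=Mode.DIFF_SF))
        assert (counts.tp, counts.fn) == (1, 1)
        assert counts.total + dropped == len(comps)
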