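"""The dual-condition correlation screen and its composite-score filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from gynoscreen import (
    GeneMap,
    TranscriptSurvivalScreen,
    gene_tally,
    normalize,
    pearson_r,
    run_screen,
    spearman_r,
)
from gynoscreen.errors import DesignError, UsageError

from conftest import GYNO_EYED, make_count_matrix

EFF = pd.Series(GYNO_EYED, index=["F1", "F2", "F3", "F4"])


def _normalized(counts, **kw):
    m = make_count_matrix(counts, **kw)
    return normalize(m, np.ones(m.n_samples))


class TestPearson:
    def test_identity_is_one(self):
        assert pearson_r([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        assert pearson_r([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self):
        x, y = [1.0, 2.0, 3.0, 5.0], [2.0, 1.0, 4.0, 6.0]
        assert pearson_r(x, y) == pytest.approx(oracles.pearson(x, y), rel=1e-12)

    def test_zero_variance_is_nan_not_zero(self):
        assert math.isnan(pearson_r([3, 3, 3, 3], [1, 2, 3, 4]))

    def test_length_mismatch_and_short_inputs_rejected(self):
        with pytest.raises(UsageError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(UsageError):
            pearson_r([1, 2], [1, 2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=8),
           a=st.floats(0.01, 100), b=st.floats(-50, 50))
    def test_invariant_under_positive_affine_transform(self, a, b, x):
        y = list(range(len(x)))
        r0 = pearson_r(x, y)
        r1 = pearson_r([a * v + b for v in x], y)
        if math.isnan(r0):
            assert math.isnan(r1)
        else:
            assert r1 == pytest.approx(r0, abs=1e-9)
            assert pearson_r([-a * v for v in x], y) == pytest.approx(-r0, abs=1e-9)

    def test_spearman_is_pearson_on_ranks(self):
        x, y = [10.0, 4.0, 7.0, 1.0], [3.5, 57.2, 3.1, 6.2]
        assert spearman_r(x, y) == pytest.approx(
            oracles.pearson(oracles.midranks(x), oracles.midranks(y)), rel=1e-12)


class TestScreen:
    def test_perfect_tracking_transcript_scores_two_and_passes(self):
        # expression equal to the efficiency vector (x10 to stay integral)
        row = [35, 572, 31, 62]
        nm = _normalized(np.array([row + row, [5] * 8]))
        res = run_screen(nm, EFF)
        top = res.candidates.iloc[0]
        assert top["transcript_id"] == "t0"
        assert top["score"] == pytest.approx(2.0, abs=1e-12)
        assert bool(top["passes"])
        assert top["direction"] == "+/+"

    def test_constant_transcript_is_undefined_and_fails(self):
        nm = _normalized(np.array([[7] * 8]))
        res = run_screen(nm, EFF)
        rec = res.candidates.iloc[0]
        assert math.isnan(rec["r_control"]) and math.isnan(rec["r_gyno"])
        assert rec["score"] == 0.0 and not rec["passes"]
        assert rec["direction"] == "na"

    def test_base_mean_filter_blocks_low_expression(self):
        # perfect correlation but tiny counts: base mean <= 1 must fail
        row = [0, 6, 0, 0]
        nm = _normalized(np.array([row + row]))
        assert nm.base_means[0] == pytest.approx(1.5)
        res_pass = run_screen(nm, EFF)
        assert res_pass.n_passing == 1
        res_block = run_screen(nm, EFF, base_mean_threshold=1.5)  # strict >
        assert res_block.n_passing == 0

    def test_missing_condition_for_female_is_design_error(self):
        samples = ["Fc1", "Fc2", "Fc3", "Fc4", "Fg1", "Fg2", "Fg3"]
        nm = _normalized(np.ones((2, 7), dtype=int), samples=samples)
        with pytest.raises(DesignError, match="F4"):
            run_screen(nm, EFF)

    @pytest.mark.parametrize("seed", range(10))
    def test_passing_set_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nm = _normalized(rng.integers(0, 30, size=(50, 8)))
        res = run_screen(nm, EFF, score_threshold=1.2)  # loose enough to pass some
        values = {t: dict(zip(nm.sample_ids, nm.values[i]))
                  for i, t in enumerate(nm.transcript_ids)}
        meta = {s: (nm.meta.loc[s, "female_id"], nm.meta.loc[s, "condition"])
                for s in nm.sample_ids}
        expected = oracles.screen_filter(values, meta, dict(EFF), 1.0, 1.2)
        assert set(res.passing_ids) == expected

    def test_row_and_column_permutation_invariance(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 30, size=(20, 8))
        nm = _normalized(counts)
        base = run_screen(nm, EFF).candidates.set_index("transcript_id")
        row_perm = rng.permutation(20)
        col_perm = rng.permutation(8)
        m2 = make_count_matrix(counts[np.ix_(row_perm, col_perm)],
                               transcript_ids=[f"t{i}" for i in row_perm],
                               samples=[nm.sample_ids[j] for j in col_perm])
        res2 = run_screen(normalize(m2, np.ones(8)), EFF)
        got = res2.candidates.set_index("transcript_id").loc[base.index]
        pd.testing.assert_frame_equal(got, base, check_exact=False, atol=1e-12)

    def test_lowering_score_threshold_never_shrinks_passing_set(self):
        rng = np.random.default_rng(8)
        nm = _normalized(rng.integers(0, 30, size=(100, 8)))
        previous: set = set()
        for thr in (1.99, 1.5, 1.0, 0.5, 0.0):
            passing = set(run_screen(nm, EFF, score_threshold=thr).passing_ids)
            assert previous <= passing
            previous = passing

    def test_sorted_by_descending_score_with_id_tiebreak(self):
        rng = np.random.default_rng(1)
        nm = _normalized(rng.integers(0, 30, size=(30, 8)))
        cand = run_screen(nm, EFF).candidates
        scores = cand["score"].to_numpy()
        assert (np.diff(scores) <= 1e-15).all()
        for s, sub in cand.groupby("score"):
            assert list(sub["transcript_id"]) == sorted(sub["transcript_id"])


class TestGeneTally:
    def _results(self, gm):
        row = [35, 572, 31, 62]
        counts = np.array([row + row, [v * 2 for v in row + row],
                           [v * 3 for v in row + row], [9] * 8])
        nm = _normalized(counts, transcript_ids=["tA", "tB", "tC", "tD"])
        return run_screen(nm, EFF, gene_map=gm)

    def test_three_transcripts_two_genes(self):
        res = self._results(GeneMap({"tA": "g1", "tB": "g1", "tC": "g2", "tD": "g3"}))
        assert gene_tally(res) == (3, 2)

    def test_unmapped_transcript_counts_as_own_gene(self):
        res = self._results(GeneMap({"tA": "g1", "tB": "g1"}))
        assert gene_tally(res) == (3, 2)  # g1 + self-mapped tC

    def test_empty_passing_set(self):
        nm = _normalized(np.ones((3, 8), dtype=int) * 5)
        res = run_screen(nm, EFF)
        assert gene_tally(res) == (0, 0)


class TestModelSurface:
    def test_fit_from_counts_and_survival(self, table1_survival):
        # constant background rows keep the size factors at exactly 1
        row = [35, 572, 31, 62]
        m = make_count_matrix(np.array([row + row, [7] * 8, [9] * 8, [11] * 8]))
        model = TranscriptSurvivalScreen(m, table1_survival)
        np.testing.assert_allclose(model.efficiency.to_numpy(), GYNO_EYED)
        res = model.fit()
        assert res.n_passing == 1
        text = res.summary()
        assert "Passing transcripts:       1" in text
        assert "F2=57.2%" in text

    def test_swimup_stage_changes_efficiency_vector(self, table1_survival):
        m = make_count_matrix(np.ones((1, 8), dtype=int))
        model = TranscriptSurvivalScreen(m, table1_survival, stage="swimup")
        np.testing.assert_allclose(model.efficiency.to_numpy(),
                                   (0.8, 41.5, 1.0, 5.0))
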