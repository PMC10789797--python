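"""Consensus of multi-engine ancestral reconstructions: votes, ties, posteriors."""

import itertools

import numpy as np
import pytest

from asgard_ogt import (
    AncestralReconstruction,
    consensus_sequence,
    disagreement_report,
    mean_posterior,
    simulate_asr_set,
)


def _rec(method, seq, pps):
    return AncestralReconstruction(method, seq, np.asarray(pps, dtype=float))


class TestConsensusSequence:
    def test_identical_inputs_give_identical_consensus(self):
        recs = [
            _rec("a", "MKV", [0.9, 0.8, 0.7]),
            _rec("b", "MKV", [0.95, 0.6, 0.75]),
            _rec("c", "MKV", [0.85, 0.9, 0.65]),
        ]
        res = consensus_sequence(recs)
        assert res.sequence == "MKV"
        assert res.disagreement_sites == ()
        # unanimous-column PP is the maximum across methods
        np.testing.assert_allclose(res.site_pp, [0.95, 0.9, 0.75])
        assert mean_posterior(res) == pytest.approx((0.95 + 0.9 + 0.75) / 3)

    def test_two_of_three_majority(self):
        recs = [
            _rec("a", "A", [0.5]),
            _rec("b", "A", [0.6]),
            _rec("c", "S", [0.99]),
        ]
        res = consensus_sequence(recs)
        assert res.aligned_sequence == "A"
        assert res.disagreement_sites == (0,)
        assert res.site_pp[0] == pytest.approx(0.6)

    def test_three_way_tie_breaks_by_posterior(self):
        recs = [
            _rec("a", "A", [0.51]),
            _rec("b", "S", [0.88]),
            _rec("c", "T", [0.60]),
        ]
        assert consensus_sequence(recs).aligned_sequence == "S"

    def test_tie_break_rule_exhaustively(self):
        # every assignment of three distinct states with distinct PPs must
        # pick the highest-PP state; verified over all orderings
        for perm in itertools.permutations([("A", 0.3), ("S", 0.9), ("T", 0.6)]):
            recs = [_rec(f"m{i}", st, [pp]) for i, (st, pp) in enumerate(perm)]
            assert consensus_sequence(recs).aligned_sequence == "S", perm

    def test_pp_tie_falls_back_to_lexicographic(self):
        recs = [
            _rec("a", "T", [0.7]),
            _rec("b", "C", [0.7]),
            _rec("c", "W", [0.7]),
        ]
        assert consensus_sequence(recs).aligned_sequence == "C"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        alphabet = "ACDEFG-"
        seqs = ["".join(rng.choice(list(alphabet), 30)) for _ in range(3)]
        pps = [np.where([c == "-" for c in s], np.nan, rng.uniform(0.4, 1.0, 30)) for s in seqs]
        recs = [_rec(f"m{i}", s, p) for i, (s, p) in enumerate(zip(seqs, pps))]
        base = consensus_sequence(recs)
        for perm in itertools.permutations(recs):
            other = consensus_sequence(list(perm))
            assert other.aligned_sequence == base.aligned_sequence
            assert other.disagreement_sites == base.disagreement_sites

    def test_gap_is_a_votable_state_and_dropped_from_export(self):
        recs = [
            _rec("a", "M-K", [0.9, np.nan, 0.8]),
            _rec("b", "M-K", [0.9, np.nan, 0.7]),
            _rec("c", "MAK", [0.9, 0.99, 0.6]),
        ]
        res = consensus_sequence(recs)
        assert res.aligned_sequence == "M-K"
        assert res.sequence == "MK"
        assert res.disagreement_sites == (1,)

    def test_residue_with_evidence_beats_gap_on_vote_tie(self):
        recs = [
            _rec("a", "-", [np.nan]),
            _rec("b", "K", [0.5]),
        ]
        assert consensus_sequence(recs).aligned_sequence == "K"

    def test_reference_mode_overrides_vote(self):
        recs = [
            _rec("a", "A", [0.9]),
            _rec("b", "A", [0.9]),
            _rec("c", "S", [0.5]),
        ]
        assert consensus_sequence(recs, reference="S").aligned_sequence == "S"
        # reference state absent from the column: normal cascade applies
        assert consensus_sequence(recs, reference="W").aligned_sequence == "A"

    def test_unequal_lengths_rejected(self):
        recs = [_rec("a", "MK", [0.9, 0.9]), _rec("b", "MKV", [0.9, 0.9, 0.9])]
        with pytest.raises(ValueError, match="align"):
            consensus_sequence(recs)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            _rec("a", "MX1", [0.9, 0.9, 0.9])

    def test_single_reconstruction_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            consensus_sequence([_rec("a", "MK", [0.9, 0.9])])


class TestMeanPosterior:
    def test_simple_mean(self):
        recs = [_rec("a", "MKV", [1.0, 0.8, 0.9]), _rec("b", "MKV", [1.0, 0.8, 0.9])]
        assert mean_posterior(consensus_sequence(recs)) == pytest.approx(0.9)

    def test_all_unanimous_all_pp_one_is_exactly_one(self):
        recs = [_rec("a", "MKVLQ", [1.0] * 5), _rec("b", "MKVLQ", [1.0] * 5)]
        assert mean_posterior(consensus_sequence(recs)) == 1.0

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(11)
        pps = rng.uniform(0.5, 1.0, 100)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        recs = [_rec("a", seq, pps), _rec("b", seq, pps)]
        expected = float(sum(pps) / len(pps))  # plain running sum as the oracle
        assert mean_posterior(consensus_sequence(recs)) == pytest.approx(expected, abs=1e-12)

    def test_all_gap_consensus_rejected(self):
        recs = [_rec("a", "--", [np.nan] * 2), _rec("b", "--", [np.nan] * 2)]
        with pytest.raises(ValueError, match="all gaps"):
            mean_posterior(consensus_sequence(recs))


class TestDisagreementReport:
    def test_identical_inputs_empty_table(self):
        recs = [_rec("a", "MKV", [0.9] * 3), _rec("b", "MKV", [0.9] * 3)]
        res = consensus_sequence(recs)
        assert len(disagreement_report(recs, res)) == 0

    def test_one_disagreeing_column_one_row(self):
        recs = [_rec("a", "MKV", [0.9] * 3), _rec("b", "MRV", [0.9] * 3)]
        res = consensus_sequence(recs)
        table = disagreement_report(recs, res)
        assert len(table) == 1
        assert table.iloc[0]["column"] == 1
        assert set(table.columns) >= {"column", "state_a", "state_b", "chosen_state", "chosen_pp"}

    def test_planted_disagreements_counted(self):
        rng = np.random.default_rng(3)
        truth = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        planted = sorted(rng.choice(60, size=7, replace=False))
        seq_b = list(truth)
        for col in planted:
            seq_b[col] = "W" if truth[col] != "W" else "Y"
        recs = [
            _rec("a", truth, np.full(60, 0.9)),
            _rec("b", "".join(seq_b), np.full(60, 0.8)),
        ]
        res = consensus_sequence(recs)
        table = disagreement_report(recs, res)
        assert len(table) == 7
        assert list(table["column"]) == planted


class TestConsensusAccuracy:
    def test_consensus_beats_best_single_method_in_expectation(self):
        # planted truth, three engines with independent per-site error; over
        # many seeds the majority-vote consensus must recover the truth at
        # least as accurately as the single best engine on average
        rng = np.random.default_rng(2024)
        truth = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
        errors = (0.08, 0.12, 0.16)
        cons_acc, best_single_acc = [], []
        for seed in range(50):
            recs = simulate_asr_set(truth, errors, seed=seed)
            res = consensus_sequence(recs)
            match = np.mean([a == b for a, b in zip(res.aligned_sequence, truth)])
            cons_acc.append(match)
            singles = [
                np.mean([a == b for a, b in zip(r.sequence, truth)]) for r in recs
            ]
            best_single_acc.append(max(singles))
        assert np.mean(cons_acc) >= np.mean(best_single_acc)
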