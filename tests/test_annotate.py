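import numpy as np
import pytest
from _toys import make_set, rank_statistic

from rtpred import annotate as A
from rtpred.molecules import MoleculeRecord, adduct_mz


class TestCandidateSearch:
    def _library(self):
        return [
            MoleculeRecord(mol_id="a", mono_mass=100.0000, rt=100.0),
            MoleculeRecord(mol_id="b", mono_mass=100.0005, rt=200.0),
            MoleculeRecord(mol_id="c", mono_mass=200.0, rt=300.0),
        ]

    def test_ppm_window_admits_near_masses_only(self):
        # query at b's protonated m/z: a is ~5 ppm away, c is far
        q = A.QueryIon("q1", adduct_mz(100.0005, "M+H"), "M+H", rt_exp=150.0)
        (cs,) = A.candidate_search([q], self._library(), tol_ppm=10)
        assert sorted(cs.candidates["mol_id"]) == ["a", "b"]
        ppm_a = cs.candidates.set_index("mol_id").loc["a", "ppm_error"]
        assert ppm_a == pytest.approx(4.95, abs=0.01)

    def test_zero_tolerance_keeps_exact_match_only(self):
        q = A.QueryIon("q1", adduct_mz(100.0005, "M+H"), "M+H", rt_exp=150.0)
        (cs,) = A.candidate_search([q], self._library(), tol_ppm=0)
        assert list(cs.candidates["mol_id"]) == ["b"]

    def test_distant_query_yields_empty_set(self):
        q = A.QueryIon("q1", 500.0, "M-H", rt_exp=150.0)
        (cs,) = A.candidate_search([q], self._library())
        assert cs.n_candidates == 0

    def test_empty_library_raises(self):
        with pytest.raises(ValueError, match="empty library"):
            A.candidate_search([], [])

    def test_widening_tolerance_never_loses_candidates(self):
        q = A.QueryIon("q1", adduct_mz(100.0005, "M+H"), "M+H", rt_exp=150.0)
        counts = [
            A.candidate_search([q], self._library(), tol_ppm=t)[0].n_candidates
            for t in (0, 2, 5, 10, 50)
        ]
        assert counts == sorted(counts)


class TestRanking:
    def test_truth_with_smallest_error_ranks_first(self):
        ordered, rank = A.rank_candidates(make_set("q", 2.0, [10.0, 30.0]))
        assert rank == 1
        assert list(ordered["mol_id"])[0] == "truth"

    def test_single_candidate_is_rank_one(self):
        _, rank = A.rank_candidates(make_set("q", 5.0, []))
        assert rank == 1

    def test_equal_errors_tie_break_by_mol_id(self):
        cs = make_set("q", 10.0, [10.0, 10.0])  # decoys d0,d1 tie with "truth"
        ordered, rank = A.rank_candidates(cs)
        assert list(ordered["mol_id"]) == ["d0", "d1", "truth"]
        assert rank == 3


class TestRocCurve:
    def hand_toy(self):
        # correct errors {5, 30}; incorrect errors {20, 50, 10, 80}
        return [make_set("q1", 5.0, [20.0, 50.0]), make_set("q2", 30.0, [10.0, 80.0])]

    def test_confusion_counts_match_hand_enumeration(self):
        roc = A.roc_curve(self.hand_toy())
        t = roc.table.set_index("threshold")
        for thr, tp, fp in [(0.0, 0, 0), (5.0, 1, 0), (10.0, 1, 1), (20.0, 1, 2), (30.0, 2, 2), (50.0, 2, 3), (80.0, 2, 4)]:
            assert t.loc[thr, "TP"] == tp and t.loc[thr, "FP"] == fp
            assert t.loc[thr, "FN"] == 2 - tp and t.loc[thr, "TN"] == 4 - fp

    def test_auc_matches_hand_value(self):
        assert A.roc_curve(self.hand_toy()).auc == pytest.approx(0.75)

    def test_youden_threshold_tie_goes_to_smallest(self):
        # J = 0.5 first reached at threshold 5.0
        assert A.select_threshold(A.roc_curve(self.hand_toy())) == 5.0

    def test_counts_partition_and_tp_fn_invariant(self):
        roc = A.roc_curve(self.hand_toy())
        total = roc.n_correct + roc.n_incorrect
        assert ((roc.table[["TP", "TN", "FP", "FN"]].sum(axis=1)) == total).all()
        assert ((roc.table["TP"] + roc.table["FN"]) == roc.n_correct).all()

    def test_perfect_separation(self):
        sets = [make_set("q1", 1.0, [40.0, 60.0]), make_set("q2", 3.0, [50.0])]
        roc = A.roc_curve(sets)
        assert roc.auc == pytest.approx(1.0)
        thr = A.select_threshold(roc)
        row = roc.table[roc.table["threshold"] == thr].iloc[0]
        assert row["TPR"] == 1.0 and row["FPR"] == 0.0

    def test_identical_distributions_give_half_auc(self, rng):
        sets = []
        for i in range(300):
            errs = rng.integers(0, 41, size=3) * 2.5
            sets.append(make_set(f"q{i}", float(errs[0]), [float(e) for e in errs[1:]]))
        assert A.roc_curve(sets).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_rank_statistic_on_grid_aligned_toys(self, rng):
        for trial in range(5):
            sets, correct, incorrect = [], [], []
            for i in range(rng.integers(3, 8)):
                errs = rng.integers(0, 41, size=rng.integers(2, 6)) * 2.5
                sets.append(make_set(f"q{i}", float(errs[0]), [float(e) for e in errs[1:]]))
                correct.append(errs[0])
                incorrect.extend(errs[1:])
            if not incorrect:
                continue
            assert A.roc_curve(sets).auc == pytest.approx(
                rank_statistic(correct, incorrect)
            )

    def test_no_truth_raises(self):
        with pytest.raises(ValueError, match="no known truth"):
            A.roc_curve([make_set("q", None, [10.0])])


class TestFiltering:
    def toy(self):
        return [
            make_set("q1", 30.0, [10.0, 70.0]),
            make_set("q2", 5.0, [40.0]),
            make_set("q3", 20.0, [25.0, 90.0]),
        ]

    def test_threshold_100_retains_everything(self):
        kept, report = A.filter_candidates(self.toy(), 100.0)
        assert report.n_before == report.n_after == 8
        assert report.n_truth_lost == 0

    def test_threshold_zero_keeps_only_zero_error(self):
        _, report = A.filter_candidates([make_set("q", 0.0, [5.0])], 0.0)
        assert report.n_after == 1 and report.n_truth_lost == 0

    def test_lost_truth_fraction_matches_hand_count(self):
        # at 27.5%: q1 loses its truth (error 30), q2 and q3 keep theirs
        kept, report = A.filter_candidates(self.toy(), 27.5)
        assert report.n_truth_present == 3
        assert report.n_truth_lost == 1
        assert report.truth_lost_fraction == pytest.approx(1 / 3)
        assert report.per_query.set_index("query_id").loc["q1", "truth_lost"]
        assert [len(s.candidates) for s in kept] == [1, 1, 2]

    def test_boundary_is_inclusive(self):
        _, report = A.filter_candidates([make_set("q", 27.5, [])], 27.5)
        assert report.n_truth_lost == 0


class TestRankingReport:
    def test_single_candidate_sets_flag_empty_cells(self):
        report = A.ranking_report([make_set(f"q{i}", 1.0, []) for i in range(4)])
        assert report.matrix.isna().all().all()
        assert np.isnan(report.top3_pct)
        assert report.n_cases == {1: 0, 2: 0, 3: 0}

    def test_hand_built_five_sets(self):
        sets = [
            make_set("s1", 1.0, [10.0, 20.0, 30.0]),          # 4 cands, rank 1
            make_set("s2", 15.0, [10.0, 20.0, 30.0]),         # 4 cands, rank 2
            make_set("s3", 40.0, [5.0, 10.0, 20.0, 50.0]),    # 5 cands, rank 4
            make_set("s4", 1.0, [99.0]),                      # 2 cands, rank 1
            make_set("s5", 25.0, [5.0, 10.0]),                # 3 cands, rank 3
        ]
        rep = A.ranking_report(sets)
        m = rep.matrix
        assert m.loc[1, ">1"] == pytest.approx(40.0)
        assert m.loc[2, ">1"] == pytest.approx(20.0)
        assert m.loc[3, ">1"] == pytest.approx(20.0)
        assert m.loc[1, ">2"] == pytest.approx(25.0)
        assert m.loc[3, ">2"] == pytest.approx(25.0)
        assert m.loc[1, ">3"] == pytest.approx(100 / 3)
        assert m.loc[3, ">3"] == pytest.approx(0.0)
        assert rep.top3_pct == pytest.approx(200 / 3)
        assert rep.n_cases == {1: 5, 2: 4, 3: 3}

    def test_top3_bounded_by_rank_components(self):
        sets = [make_set(f"q{i}", float(5 * i), [1.0, 2.0, 3.0, 4.0]) for i in range(6)]
        rep = A.ranking_report(sets)
        parts = rep.matrix[">3"].fillna(0)
        assert rep.top3_pct == pytest.approx(parts.sum())


class TestQueryCsv:
    def test_roundtrip(self, tmp_path):
        queries = [
            A.QueryIon("q1", 101.007276, "M+H", 120.0, "m1"),
            A.QueryIon("q2", 98.992724, "M-H", 240.0, None),
        ]
        path = tmp_path / "queries.csv"
        A.write_query_csv(queries, str(path))
        back = A.read_query_csv(str(path))
        assert [q.query_id for q in back] == ["q1", "q2"]
        assert back[0].true_mol_id == "m1" and back[1].true_mol_id is None
        assert back[1].adduct == "M-H"
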