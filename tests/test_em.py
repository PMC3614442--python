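"""EM on incomplete records: hand-checked E/M steps, monotone likelihood,
parameter recovery, and the candidate-structure comparison."""

import numpy as np
import pandas as pd
import pytest

from bnepi import (
    DataTable,
    NetworkStructure,
    ParameterSet,
    ancestral_sample,
    candidate_structures,
    compare_candidates,
    e_step,
    em_fit,
    init_from_complete_cases,
    inject_mcar,
    m_step,
)
from bnepi.em import expected_scores
from bnepi.scoring import score_structure


@pytest.fixture(scope="module")
def two_node():
    s = NetworkStructure(["A", "B"], None, [("A", "B")])
    p = ParameterSet(
        s,
        {
            "A": np.array([[0.5, 0.5]]),
            "B": np.array([[0.9, 0.1], [0.1, 0.9]]),
        },
    )
    return s, p


class TestInit:
    def test_complete_data_matches_mle(self, nets):
        structure, params = nets["chain3"]
        data = ancestral_sample(structure, params, 1000, seed=301)
        init = init_from_complete_cases(data, structure)
        counts_b = np.zeros((2, 2))
        a = data.df["A"].astype(int).to_numpy()
        b = data.df["B"].astype(int).to_numpy()
        for j in range(2):
            counts_b[j] = np.bincount(b[a == j], minlength=2)
        expected = counts_b / counts_b.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(init["B"], expected, atol=1e-12)

    def test_published_style_initialization_representable(self):
        """The worked-example initialization (binary E, S1, C with C's CPT
        indexed by both parents) is exactly representable."""
        s = NetworkStructure(
            ["E", "S1", "C"], None, [("E", "C"), ("S1", "C")]
        )
        p = ParameterSet(
            s,
            {
                "E": np.array([[1 - 0.583, 0.583]]),
                "S1": np.array([[1 - 0.350, 0.350]]),
                "C": np.array(
                    [
                        [1 - 0.033, 0.033],
                        [1 - 0.014, 0.014],
                        [1 - 0.026, 0.026],
                        [1 - 0.024, 0.024],
                    ]
                ),
            },
        )
        assert p.prob("E", "1", {}) == pytest.approx(0.583)
        assert p.prob("C", "1", {"E": "0", "S1": "0"}) == pytest.approx(0.033)
        assert p.prob("C", "1", {"E": "1", "S1": "0"}) == pytest.approx(0.026)

    def test_entirely_missing_column_uniform(self):
        s = NetworkStructure(["A", "B"], None, [])
        df = pd.DataFrame({"A": ["0", "1", "1"], "B": [None, None, None]})
        init = init_from_complete_cases(DataTable(df), s)
        np.testing.assert_allclose(init["B"], [[0.5, 0.5]])


class TestESandMSteps:
    def test_no_missing_cells_weight_one(self, two_node):
        s, p = two_node
        data = DataTable(pd.DataFrame({"A": ["0", "1"], "B": ["1", "0"]}))
        frac = e_step(data, s, p)
        assert np.all(frac.weights == 1.0)
        assert frac.n_records == 2

    def test_hand_bayes_posterior(self, two_node):
        """Record (A=?, B=1): weight(A=1) = 0.9 / (0.9 + 0.1) = 0.9."""
        s, p = two_node
        data = DataTable(pd.DataFrame({"A": [None], "B": ["1"]}))
        frac = e_step(data, s, p)
        w = {
            tuple(row): weight
            for row, weight in zip(frac.codes.tolist(), frac.weights)
        }
        assert w[(1, 1)] == pytest.approx(0.9)
        assert w[(0, 1)] == pytest.approx(0.1)

    def test_weights_sum_to_one_per_record(self, nets):
        structure, params = nets["chain3"]
        data = inject_mcar(
            ancestral_sample(structure, params, 1000, seed=303), 0.3, seed=304
        )
        frac = e_step(data, structure, params)
        sums = np.bincount(frac.record_ids, weights=frac.weights)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_m_step_weighted_frequencies(self):
        s = NetworkStructure(["A"])
        p = ParameterSet(s, {"A": np.array([[0.5, 0.5]])})
        data = DataTable(pd.DataFrame({"A": ["1", None]}))
        # posterior for the missing record under uniform prior: (0.5, 0.5);
        # build the fractional table by hand to use weights 0.75 / 0.25
        frac = e_step(data, s, p)
        frac.weights = np.array([1.0, 0.75, 0.25][: len(frac.weights)])
        # completions enumerate state 0 then state 1 for the missing cell
        order = frac.codes[frac.record_ids == 1][:, 0]
        w = dict(zip(order.tolist(), frac.weights[frac.record_ids == 1]))
        frac.weights[frac.record_ids == 1] = [w[0], w[1]]
        est = m_step(frac)
        assert est["A"][0, 1] == pytest.approx((1.0 + w[1]) / 2.0)

    def test_fixed_point_idempotence(self, two_node):
        s, _ = two_node
        data = DataTable(
            pd.DataFrame(
                {"A": ["0", "0", "1", "1", None], "B": ["0", "1", "1", "1", "1"]}
            )
        )
        result = em_fit(data, s, tolerance=1e-12, max_iter=2000)
        theta = result.params
        again = m_step(e_step(data, s, theta))
        for v in s.nodes:
            np.testing.assert_allclose(again[v], theta[v], atol=1e-9)


class TestEMFit:
    def test_complete_data_converges_immediately_to_mle(self, nets):
        structure, params = nets["chain3"]
        data = ancestral_sample(structure, params, 500, seed=305)
        result = em_fit(data, structure)
        assert result.converged
        assert result.n_iter <= 2
        mle = init_from_complete_cases(data, structure)
        for v in structure.nodes:
            np.testing.assert_allclose(result.params[v], mle[v], atol=1e-12)

    def test_loglik_monotone_over_seeds(self, nets):
        structure, params = nets["chain3"]
        for seed in range(20):
            data = inject_mcar(
                ancestral_sample(structure, params, 400, seed=400 + seed),
                0.25,
                seed=500 + seed,
            )
            result = em_fit(data, structure)
            trace = result.loglik_trace
            assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_parameter_recovery_under_mcar(self, nets):
        """CPTs recovered within 0.05 with 30% MCAR in one column."""
        structure, params = nets["chain3"]
        data = ancestral_sample(structure, params, 2000, seed=307)
        data = inject_mcar(data, 0.3, protected=("A", "C"), seed=308)
        result = em_fit(data, structure)
        assert result.converged
        for v in structure.nodes:
            np.testing.assert_allclose(result.params[v], params[v], atol=0.05)

    def test_nonconvergence_flagged_but_returned(self, nets):
        structure, params = nets["chain3"]
        data = inject_mcar(
            ancestral_sample(structure, params, 500, seed=309), 0.3, seed=310
        )
        result = em_fit(data, structure, tolerance=1e-15, max_iter=2)
        assert not result.converged
        assert result.n_iter == 2

    def test_missing_cap_drops_records(self, nets):
        structure, params = nets["chain3"]
        df = ancestral_sample(structure, params, 50, seed=311).df
        df.loc[0, ["A", "B", "C"]] = None
        result = em_fit(DataTable(df), structure, missing_cap=2)
        assert result.completed.n_dropped == 1


class TestCandidates:
    @pytest.fixture
    def base_net(self, bladder11):
        return bladder11[0]

    def test_five_candidates_for_outcome_with_two_children(self, base_net):
        cands = candidate_structures(base_net, "TOENAIL_AS", "CANCER")
        labels = [label for label, _ in cands]
        assert labels == [
            "none",
            "TOENAIL_AS -> CANCER",
            "CANCER -> TOENAIL_AS",
            "TOENAIL_AS -> SMOKER",
            "TOENAIL_AS -> XRCC3_241",
        ]

    def test_childless_outcome_gives_three(self):
        s = NetworkStructure(["Y", "T", "Z"], None, [("Z", "Y")])
        cands = candidate_structures(s, "T", "Y")
        assert len(cands) == 3

    def test_cycle_creating_candidate_excluded(self):
        # T is an ancestor of Y: the Y -> T candidate would close a cycle
        s = NetworkStructure(
            ["T", "M", "Y", "C"], None, [("T", "M"), ("M", "Y"), ("Y", "C")]
        )
        cands = candidate_structures(s, "T", "Y")
        labels = {label for label, _ in cands}
        assert "Y -> T" not in labels
        assert "T -> Y" in labels  # still fine: T -> Y shortcuts, no cycle

    def test_target_already_in_blanket_rejected(self, base_net):
        with pytest.raises(ValueError, match="already"):
            candidate_structures(base_net, "GENDER", "CANCER")

    def test_zero_missingness_reduces_to_plain_scoring(self, nets):
        structure, params = nets["chain3"]
        data = ancestral_sample(structure, params, 600, seed=313)
        base = data.infer_structure([("A", "B")])
        cands = candidate_structures(base, "C", "B")
        table = compare_candidates(data, cands)
        for label, rep in table.rows:
            direct = score_structure(data, dict(cands)[label])
            assert rep.loglik == pytest.approx(direct.loglik, abs=1e-9)
            assert rep.bic == pytest.approx(direct.bic, abs=1e-9)

    def test_rows_satisfy_aic_identity(self, nets):
        structure, params = nets["chain3"]
        data = inject_mcar(
            ancestral_sample(structure, params, 500, seed=315), 0.2, seed=316
        )
        base = data.infer_structure([("A", "B")])
        table = compare_candidates(data, candidate_structures(base, "C", "B"))
        for label, rep in table.rows:
            assert rep.aic - rep.loglik == pytest.approx(-rep.n_params, abs=1e-9)
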