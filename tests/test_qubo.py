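"""QUBO construction, algebra, penalty and Ising conversion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quboselect import (
    GeneratorConfig,
    IsingModel,
    QuboMatrix,
    add_cardinality_penalty,
    build_qubo,
    entropy,
    evaluate,
    generate,
    ising_from_qubo,
    lambda_auto,
    qubo_from_ising,
)
from quboselect.synthetic import SurveyTable


def evaluate_oracle(Q: np.ndarray, x: np.ndarray) -> float:
    """Naive double loop over Eq-style terms."""
    total = 0.0
    p = Q.shape[0]
    for i in range(p):
        total += Q[i, i] * x[i]
        for j in range(i + 1, p):
            total += Q[i, j] * x[i] * x[j]
    return total


def all_bits(p: int) -> np.ndarray:
    return np.array(list(itertools.product([0, 1], repeat=p)))


class TestEvaluate:
    def test_all_zeros_gives_zero(self):
        Q = QuboMatrix(np.triu(np.arange(9.0).reshape(3, 3)))
        assert evaluate(Q, [0, 0, 0]) == 0.0

    def test_unit_vector_picks_diagonal(self):
        Q = QuboMatrix(np.triu(np.arange(9.0).reshape(3, 3)))
        assert evaluate(Q, [0, 1, 0]) == Q.Q[1, 1]

    def test_hand_example(self):
        Q = QuboMatrix(np.array([[1.0, -3.0], [0.0, 2.0]]))
        assert evaluate(Q, [1, 1]) == 0.0

    def test_dimension_mismatch_rejected(self):
        Q = QuboMatrix(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="shape"):
            evaluate(Q, [1, 0, 1])

    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            p = int(rng.integers(2, 9))
            Q = np.triu(rng.normal(size=(p, p)))
            x = rng.integers(0, 2, size=p)
            assert evaluate(QuboMatrix(Q), x) == pytest.approx(
                evaluate_oracle(Q, x), abs=1e-10
            )

    def test_lower_triangle_rejected(self):
        with pytest.raises(ValueError, match="upper-triangular"):
            QuboMatrix(np.ones((2, 2)))


def _table_from_codes(codes: np.ndarray, y: np.ndarray) -> SurveyTable:
    names = [f"f{i+1}" for i in range(codes.shape[1])]
    return SurveyTable(
        features=pd.DataFrame(codes, columns=names),
        target=pd.Series(y, name="target"),
    )


class TestBuildQubo:
    def test_pure_noise_features_give_near_zero_entries(self):
        cfg = GeneratorConfig(
            n_respondents=2000, n_relevant=0, n_redundant=0, n_noise=2,
            effect_size=0.0, noise_sd=1.0, seed=9,
        )
        table, _ = generate(cfg)
        Q = build_qubo(table).Q
        assert np.abs(Q).max() < 0.02

    def test_duplicated_feature_pays_its_own_entropy(self, rng):
        codes = rng.integers(0, 4, size=(400, 1))
        table = _table_from_codes(np.hstack([codes, codes]), rng.normal(size=400))
        Q = build_qubo(table)
        assert Q.Q[0, 1] == pytest.approx(entropy(codes[:, 0]), abs=1e-12)

    def test_literal_sign_structure(self, small_table):
        table, _ = small_table
        Q = build_qubo(table, mode="literal").Q
        assert (np.diag(Q) <= 1e-12).all()
        off = Q[np.triu_indices(Q.shape[0], k=1)]
        assert (off >= -1e-12).all()

    def test_entries_match_plugin_recomputation(self, rng):
        # 6-feature table; every entry of every mode vs direct estimators
        from quboselect import (
            BinningRule,
            conditional_mutual_information,
            discretize,
            mutual_information,
        )

        cfg = GeneratorConfig(
            n_respondents=250, n_relevant=2, n_redundant=2, n_noise=2, seed=21
        )
        table, _ = generate(cfg)
        X = table.X
        yb = discretize(table.y, BinningRule())
        for mode in ("literal", "miqubo", "conditional_diag"):
            Q = build_qubo(table, mode=mode).Q
            for i in range(6):
                if mode in ("literal", "miqubo"):
                    want = -mutual_information(X[:, i], yb)
                else:
                    want = -np.mean(
                        [
                            conditional_mutual_information(X[:, i], yb, X[:, j])
                            for j in range(6)
                            if j != i
                        ]
                    )
                assert Q[i, i] == pytest.approx(want, abs=1e-12)
                for j in range(i + 1, 6):
                    if mode == "miqubo":
                        want = -0.5 * (
                            conditional_mutual_information(X[:, i], yb, X[:, j])
                            + conditional_mutual_information(X[:, j], yb, X[:, i])
                        )
                    else:
                        want = mutual_information(X[:, i], X[:, j])
                    assert Q[i, j] == pytest.approx(want, abs=1e-12)

    def test_unknown_mode_rejected(self, small_table):
        with pytest.raises(ValueError, match="mode"):
            build_qubo(small_table[0], mode="bogus")


class TestCardinalityPenalty:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_penalty_identity_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 10))
        Q = QuboMatrix(np.triu(rng.normal(size=(p, p))))
        k = int(rng.integers(1, p + 1))
        lam = float(rng.uniform(0.1, 5.0))
        Qp = add_cardinality_penalty(Q, k, lam)
        x = rng.integers(0, 2, size=p)
        f = evaluate(Q, x)
        fp = evaluate(Qp, x) + Qp.constant
        assert fp - f == pytest.approx(lam * (x.sum() - k) ** 2, abs=1e-9)

    def test_zero_qubo_minimizers_have_exact_weight(self):
        Q = QuboMatrix(np.zeros((3, 3)))
        Qp = add_cardinality_penalty(Q, k=2, lam=1.0)
        energies = {
            tuple(x): evaluate(Qp, np.array(x)) for x in all_bits(3)
        }
        best = min(energies.values())
        argmins = {x for x, e in energies.items() if e == best}
        assert argmins == {(1, 1, 0), (1, 0, 1), (0, 1, 1)}

    def test_k_equals_p_prefers_all_ones(self):
        Q = QuboMatrix(np.zeros((4, 4)))
        Qp = add_cardinality_penalty(Q, k=4, lam=2.0)
        energies = [evaluate(Qp, x) for x in all_bits(4)]
        assert np.argmin(energies) == len(energies) - 1  # all-ones listed last

    def test_k_out_of_range_rejected(self):
        Q = QuboMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="k="):
            add_cardinality_penalty(Q, k=4, lam=1.0)

    def test_lambda_auto_forces_feasible_minimizers(self, rng):
        # every exact minimizer has exactly k ones, by enumeration
        for _ in range(5):
            p = 10
            Q = QuboMatrix(np.triu(rng.normal(size=(p, p))))
            lam = lambda_auto(Q)
            bits = all_bits(p)
            for k in (1, 3, 7, 10):
                Qp = add_cardinality_penalty(Q, k, lam)
                energies = np.array([evaluate(Qp, x) for x in bits])
                argmins = bits[energies <= energies.min() + 1e-12]
                assert (argmins.sum(axis=1) == k).all()


class TestIsingConversion:
    def test_zero_qubo_maps_to_zero_ising(self):
        model = ising_from_qubo(QuboMatrix(np.zeros((3, 3))))
        assert not model.h.any() and not model.J.any() and model.offset == 0.0

    def test_state_energy_ordering_preserved(self, rng):
        Q = QuboMatrix(np.triu(rng.normal(size=(4, 4))))
        model = ising_from_qubo(Q)
        for x in all_bits(4):
            s = 2 * x - 1
            assert evaluate(Q, x) == pytest.approx(model.energy(s), abs=1e-10)

    def test_round_trip_recovers_q(self, rng):
        Q = QuboMatrix(np.triu(rng.normal(size=(6, 6))))
        back = qubo_from_ising(ising_from_qubo(Q))
        assert np.abs(back.Q - Q.Q).max() < 1e-12
        assert back.constant == pytest.approx(0.0, abs=1e-12)

    def test_strictly_upper_triangular_couplings_enforced(self):
        with pytest.raises(ValueError, match="upper-triangular"):
            IsingModel(h=np.zeros(2), J=np.eye(2))


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path, rng):
        Q = QuboMatrix(
            np.triu(rng.normal(size=(5, 5))), metadata={"mode": "literal", "n": 100}
        )
        Q.to_files(tmp_path / "q.tsv")
        back = QuboMatrix.from_files(tmp_path / "q.tsv")
        np.testing.assert_allclose(back.Q, Q.Q, atol=0)  # repr round-trip is exact
        assert back.metadata["mode"] == "literal"
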