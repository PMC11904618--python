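"""Parameter subset selection: elimination order, threshold ladders and the
verification error norm, cross-checked against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pkident as pk
from pkident.pss import (
    EliminationTrace,
    eliminate_order,
    relative_error_norm,
    subsets_for_thresholds,
)

# ---------------------------------------------------------------------------
# Independent oracle: re-forms the reduced matrix and decomposes the Gram
# matrix by symmetric eigendecomposition at every step (different code path
# from the implementation's incremental column masking + SVD).
# ---------------------------------------------------------------------------


def oracle_elimination(A):
    A = np.array(A, dtype=float)
    names = list(range(A.shape[1]))
    order = []
    while len(names) > 1:
        M = A[:, names]
        w, V = np.linalg.eigh(M.T @ M)  # ascending eigenvalues = squared svals
        ratio = w[0] / w[-1]
        v_min = V[:, 0]
        m = np.abs(v_min)
        tied = np.flatnonzero(m >= m.max() * (1 - 1e-9))
        kill = tied[np.argmax([names[t] for t in tied])]
        order.append((names[kill], max(ratio, 0.0)))
        names.pop(kill)
    return order


def test_duplicate_columns_give_zero_ratio_and_tie_rule():
    rng = np.random.default_rng(0)
    A = np.zeros((8, 4))
    A[:, 0] = rng.standard_normal(8)
    A[:, 3] = rng.standard_normal(8)
    dup = rng.standard_normal(8)
    A[:, 1] = dup
    A[:, 2] = dup  # exact rank deficiency between columns 1 and 2
    trace = eliminate_order(A)
    first_name, first_ratio = trace.order[0]
    assert first_ratio < 1e-20
    assert first_name == "p2"  # tie resolves to the highest column index


def test_orthogonal_equal_norm_matrix_keeps_everything():
    A = np.vstack([np.eye(4), np.zeros((8, 4))])
    trace = eliminate_order(A)
    assert trace.order[0][1] == pytest.approx(1.0)
    ladder = subsets_for_thresholds(trace, [0.9, 1e-6])
    assert ladder.subsets[0] == ["p0", "p1", "p2", "p3"]
    assert ladder.subsets[1] == ["p0", "p1", "p2", "p3"]


def test_elimination_matches_oracle_on_seeded_matrices():
    rng = np.random.default_rng(1234)
    for _ in range(50):
        n = int(rng.integers(6, 21))
        p = int(rng.integers(2, min(n, 6) + 1))
        A = rng.standard_normal((n, p))
        trace = eliminate_order(A)
        expected = oracle_elimination(A)
        assert [name for name, _ in trace.order] == [f"p{j}" for j, _ in expected]
        got = np.array([r for _, r in trace.order])
        want = np.array([r for _, r in expected])
        assert np.allclose(got, want, rtol=1e-6, atol=1e-12)


def test_stopping_rule_hand_trace():
    # ratios before each elimination: 0, 1e-9, 1e-7, 1 on five parameters;
    # at eta = 2.5e-8 elimination stops at the 3-column matrix (ratio 1e-7)
    trace = EliminationTrace(
        parameter_names=["a", "b", "c", "d", "e"],
        order=[("e", 0.0), ("d", 1e-9), ("c", 1e-7), ("b", 1.0)],
    )
    ladder = subsets_for_thresholds(trace, [2.5e-8])
    assert ladder.subsets[0] == ["a", "b", "c"]


def test_threshold_below_all_ratios_returns_full_set():
    trace = EliminationTrace(
        parameter_names=["a", "b", "c"], order=[("c", 1e-4), ("b", 0.5)]
    )
    ladder = subsets_for_thresholds(trace, [1e-6])
    assert ladder.subsets[0] == ["a", "b", "c"]


def test_ladder_is_nested_and_threshold_independent():
    rng = np.random.default_rng(7)
    # ill-conditioned random matrix so the ladder actually steps
    A = rng.standard_normal((30, 6)) @ np.diag([1, 1e-1, 1e-3, 1e-4, 1e-6, 1e-8])
    trace = eliminate_order(A)
    etas = [2.5e-8, 1e-8, 2.5e-10, 1e-10, 1e-12]
    ladder = subsets_for_thresholds(trace, etas)
    sizes = [len(s) for s in ladder.subsets]
    assert sizes == sorted(sizes)
    for a, b in zip(ladder.subsets, ladder.subsets[1:]):
        assert set(a) <= set(b)
    # ladders for different threshold lists agree on shared thresholds
    partial = subsets_for_thresholds(trace, [1e-8, 1e-12])
    assert partial.subsets[0] == ladder.subsets[1]
    assert partial.subsets[1] == ladder.subsets[4]


def test_threshold_validation():
    trace = EliminationTrace(parameter_names=["a", "b"], order=[("b", 0.5)])
    with pytest.raises(ValueError, match="outside"):
        subsets_for_thresholds(trace, [1.5])
    with pytest.raises(ValueError, match="decreasing"):
        subsets_for_thresholds(trace, [1e-8, 1e-8])
    with pytest.raises(ValueError, match="empty"):
        subsets_for_thresholds(trace, [])


def test_all_zero_matrix_rejected():
    with pytest.raises(ValueError, match="no identifiable"):
        eliminate_order(np.zeros((5, 3)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_nesting_property_random_matrices(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 15))
    p = int(rng.integers(2, 6))
    A = rng.standard_normal((n, p)) * np.exp(rng.normal(0, 3, size=p))
    trace = eliminate_order(A)
    etas = sorted({float(10 ** -rng.uniform(0, 16)) for _ in range(4)}, reverse=True)
    ladder = subsets_for_thresholds(trace, etas)
    for a, b in zip(ladder.subsets, ladder.subsets[1:]):
        assert set(a) <= set(b)


class TestRelativeErrorNorm:
    def test_full_subset_is_zero(self, onecomp, grid):
        assert relative_error_norm(onecomp, grid, ["F", "V", "CL"]) == 0.0

    def test_compensating_subset_is_near_zero(self, onecomp, grid):
        # C depends only on F/V and CL/V: F and CL absorb any V perturbation
        rbar = relative_error_norm(onecomp, grid, ["F", "CL"])
        assert rbar < 1e-6

    def test_uniform_scaling_symmetry_gives_zero(self, onecomp, grid):
        # perturbing F and V by the same factor is a symmetry of the
        # one-compartment response (it depends only on F/V and CL/V), so CL
        # can always compensate exactly
        rbar = relative_error_norm(onecomp, grid, ["CL"])
        assert rbar < 1e-8

    def test_insufficient_subset_is_positive(self, twocomp, grid):
        # no such symmetry in the two-compartment model: CL alone cannot
        # absorb perturbations of the volumes and inter-compartment flow
        rbar = relative_error_norm(twocomp, grid, ["CL"])
        assert rbar > 1e-4

    def test_empty_subset_rejected(self, onecomp, grid):
        with pytest.raises(ValueError, match="nonempty"):
            relative_error_norm(onecomp, grid, [])
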