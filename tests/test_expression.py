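"""Paired differential expression: fold changes, BH, thresholds, joins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borg import (
    PairedExpressionMatrix,
    bh_adjust,
    intersect_with_candidates,
    paired_de,
    score_candidates,
)
from borg.errors import InputError
from borg.expression import signed_fold_change
from borg.prioritize import apply_criteria

from .oracles import bh_step_up
from .test_prioritize import GO_SIG, MP_SIG, fake_path


def matrix_from(values: dict[str, list[float]], n_pairs: int) -> PairedExpressionMatrix:
    d_cols = [f"D{i}" for i in range(n_pairs)]
    h_cols = [f"H{i}" for i in range(n_pairs)]
    frame = pd.DataFrame(values, index=d_cols + h_cols).T
    return PairedExpressionMatrix(frame, list(zip(d_cols, h_cols)))


def test_null_gene_has_unit_fold_change():
    mat = matrix_from({"G": [5.0, 7.0, 9.0, 5.0, 7.0, 9.0]}, 3)
    (res,) = paired_de(mat)
    assert res.fold_change == 1.0
    assert not res.is_de


def test_exact_doubling_and_halving():
    healthy = [4.0, 8.0, 16.0]
    up = matrix_from({"G": [2 * v for v in healthy] + healthy}, 3)
    assert paired_de(up)[0].fold_change == pytest.approx(2.0)
    down = matrix_from({"G": healthy + [2 * v for v in healthy]}, 3)
    assert paired_de(down)[0].fold_change == pytest.approx(-2.0)


def test_fold_change_boundary_is_strict():
    """|FC| of exactly 1.5 is not differentially expressed."""
    healthy = [10.0, 20.0, 40.0, 80.0]
    mat = matrix_from({"G": [1.5 * v for v in healthy] + healthy}, 4)
    (res,) = paired_de(mat)
    assert res.fold_change == pytest.approx(1.5)
    assert res.p_value == 0.0  # zero-variance exact ratio
    assert not res.is_de  # fails the strict > 1.5 rule despite p == 0


def test_swapping_columns_negates_every_fold_change():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(
        rng.lognormal(3, 0.4, size=(20, 10)),
        index=[f"G{i}" for i in range(20)],
        columns=[f"S{i}" for i in range(10)],
    )
    pairs = [(f"S{i}", f"S{i+5}") for i in range(5)]
    flipped = [(h, d) for d, h in pairs]
    fc = [r.fold_change for r in paired_de(PairedExpressionMatrix(frame, pairs))]
    fc_flip = [r.fold_change for r in paired_de(PairedExpressionMatrix(frame, flipped))]
    assert np.allclose(np.abs(fc), np.abs(fc_flip))  # |FC| invariant
    assert np.allclose(np.sign(fc), -np.sign(fc_flip))
    assert all(abs(f) >= 1 for f in fc)
    assert signed_fold_change(0.5) == -2.0 and signed_fold_change(2.0) == 2.0


def test_matrix_validation():
    with pytest.raises(InputError, match="duplicate"):
        matrix_from_dupe = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["G", "G"], columns=["D0", "H0"]
        )
        PairedExpressionMatrix(matrix_from_dupe, [("D0", "H0")])
    with pytest.raises(InputError, match="twice"):
        frame = pd.DataFrame([[1.0, 2.0]], index=["G"], columns=["D0", "H0"])
        PairedExpressionMatrix(frame, [("D0", "D0")])
    with pytest.raises(InputError, match="non-positive"):
        frame = pd.DataFrame([[1.0, 0.0]], index=["G"], columns=["D0", "H0"])
        PairedExpressionMatrix(frame, [("D0", "H0")])


def test_insufficient_pairs():
    frame = pd.DataFrame([[1.0, 2.0]], index=["G"], columns=["D0", "H0"])
    mat = PairedExpressionMatrix(frame, [("D0", "H0")])
    with pytest.raises(InputError, match="at least 2"):
        paired_de(mat)


def test_adjusted_p_never_below_raw():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(
        rng.lognormal(5, 0.3, size=(50, 12)),
        index=[f"G{i}" for i in range(50)],
        columns=[f"S{i}" for i in range(12)],
    )
    results = paired_de(
        PairedExpressionMatrix(frame, [(f"S{i}", f"S{i+6}") for i in range(6)])
    )
    assert all(r.p_adjusted >= r.p_value for r in results)


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_single_p_unchanged():
    assert bh_adjust([0.37]) == [0.37]


def test_bh_hand_computed_example():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_rejects_out_of_range():
    with pytest.raises(InputError):
        bh_adjust([0.5, 1.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
def test_bh_matches_brute_force_step_up(p_values):
    assert np.allclose(bh_adjust(p_values), bh_step_up(p_values), atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30),
    st.randoms(use_true_random=False),
)
def test_bh_output_follows_input_order_under_permutation(p_values, rnd):
    adjusted = bh_adjust(p_values)
    perm = list(range(len(p_values)))
    rnd.shuffle(perm)
    permuted = bh_adjust([p_values[i] for i in perm])
    assert np.allclose([adjusted[i] for i in perm], permuted, atol=1e-12)


# ---------------------------------------------------------------------------
# intersection with graph candidates


def de_result_fixture():
    mat = matrix_from(
        {
            "UP": [40.0, 44.0, 36.0, 10.0, 11.0, 9.0],
            "FLAT": [10.0, 11.0, 9.0, 10.0, 11.0, 9.0],
        },
        3,
    )
    return paired_de(mat)


def test_disjoint_symbols_give_empty_join():
    de = de_result_fixture()
    scores = score_candidates({"OTHER": [fake_path(GO_SIG)]})
    table = intersect_with_candidates(de, scores)
    assert table.empty


def test_join_keeps_de_genes_with_paths_only():
    de = de_result_fixture()
    scores = score_candidates(
        {"UP": [fake_path(GO_SIG)] * 11 + [fake_path(MP_SIG)],
         "FLAT": [fake_path(GO_SIG)]}
    )
    apply_criteria(scores, {"UP"})
    table = intersect_with_candidates(de, scores)
    assert list(table["symbol"]) == ["UP"]
    row = table.iloc[0]
    assert row["fold_change"] > 1.5
    assert row["strong"] and row["many_paths"] and row["multi_domain"]
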