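"""Canonical correspondence analysis against independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

import coccomorph as cm


def brute_force_eigenvalues(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Explicit construction: chi-square residuals, weighted projector
    matrix, full eigen-decomposition of the constrained cross-product."""
    total = Y.sum()
    P = Y / total
    r, c = P.sum(axis=1), P.sum(axis=0)
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    xm = r @ X
    xc = X - xm
    xs = np.sqrt(r @ xc**2)
    Xw = np.sqrt(r)[:, None] * (xc / xs)
    H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T  # weighted hat matrix
    Qhat = H @ Qbar
    vals = np.linalg.eigvalsh(Qhat.T @ Qhat)
    vals = np.sort(vals)[::-1]
    return vals[vals > 1e-12]


TOY_Y = np.array([[10.0, 2.0, 1.0],
                  [8.0, 4.0, 2.0],
                  [2.0, 6.0, 7.0],
                  [1.0, 3.0, 9.0]])
TOY_X = np.array([[0.1, 2.0],
                  [0.3, 1.0],
                  [0.7, 1.5],
                  [0.9, 0.2]])


def test_toy_table_eigenvalues_match_brute_force_oracle():
    res = cm.cca(pd.DataFrame(TOY_Y), pd.DataFrame(TOY_X, columns=["e1", "e2"]))
    expected = brute_force_eigenvalues(TOY_Y, TOY_X)
    assert np.allclose(res.eigenvalues, expected[:len(res.eigenvalues)],
                       atol=1e-10)


def test_eigenvalues_match_skbio_reference():
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    rng = np.random.default_rng(5)
    Y = pd.DataFrame(rng.integers(1, 40, size=(9, 5)).astype(float),
                     columns=list("abcde"))
    X = pd.DataFrame({"e1": rng.normal(size=9), "e2": rng.normal(size=9),
                      "e3": rng.normal(size=9)})
    ours = cm.cca(Y, X)
    ref = skbio_ord.cca(Y, X)
    k = len(ours.eigenvalues)
    assert np.allclose(ours.eigenvalues, np.asarray(ref.eigvals)[:k],
                       atol=1e-10)


def test_single_env_variable_gives_one_axis_with_all_inertia():
    res = cm.cca(pd.DataFrame(TOY_Y), pd.DataFrame(TOY_X[:, :1], columns=["e"]))
    assert len(res.eigenvalues) == 1
    assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-9)


def test_duplicated_env_column_dropped_and_equivalent():
    X2 = pd.DataFrame({"e": TOY_X[:, 0], "e_copy": TOY_X[:, 0]})
    with pytest.warns(UserWarning, match="collinear"):
        res2 = cm.cca(pd.DataFrame(TOY_Y), X2)
    res1 = cm.cca(pd.DataFrame(TOY_Y), pd.DataFrame({"e": TOY_X[:, 0]}))
    assert res2.dropped_env_columns == ("e_copy",)
    assert np.allclose(res2.eigenvalues, res1.eigenvalues, atol=1e-12)


def test_eigenvalue_bounds_and_ordering(rng):
    Y = pd.DataFrame(rng.integers(0, 30, size=(12, 6)).astype(float) + 0.0)
    Y.iloc[:, 0] += 1  # avoid all-zero columns
    Y["rowfix"] = 1.0  # avoid all-zero rows
    X = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
    res = cm.cca(Y, X)
    assert np.all(res.eigenvalues >= 0)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)
    assert np.all(res.eigenvalues <= 1.0 + 1e-9)  # CA upper bound
    assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
    assert np.all(np.abs(res.env_axis_scores.to_numpy()) <= 1.0 + 1e-9)
    assert res.constrained_inertia <= res.total_inertia + 1e-12


def test_sample_order_permutation_leaves_eigenvalues_unchanged(rng):
    Y = pd.DataFrame(TOY_Y)
    X = pd.DataFrame(TOY_X, columns=["e1", "e2"])
    perm = rng.permutation(len(Y))
    res = cm.cca(Y, X)
    res_p = cm.cca(Y.iloc[perm].reset_index(drop=True),
                   X.iloc[perm].reset_index(drop=True))
    assert np.allclose(res.eigenvalues, res_p.eigenvalues, atol=1e-12)


def test_all_zero_row_removed_with_warning():
    Y = pd.DataFrame(np.vstack([TOY_Y, np.zeros(3)]))
    X = pd.DataFrame(np.vstack([TOY_X, [0.5, 0.5]]), columns=["e1", "e2"])
    with pytest.warns(UserWarning, match="all-zero"):
        res = cm.cca(Y, X)
    ref = cm.cca(pd.DataFrame(TOY_Y), pd.DataFrame(TOY_X, columns=["e1", "e2"]))
    assert res.dropped_sample_rows == (4,)
    assert np.allclose(res.eigenvalues, ref.eigenvalues, atol=1e-12)


def test_negative_abundance_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        cm.cca(pd.DataFrame(-TOY_Y), pd.DataFrame(TOY_X))


def test_wa_and_lc_site_scores_both_available():
    est = cm.CanonicalCorrespondenceAnalysis(site_score_type="lc")
    est.fit(pd.DataFrame(TOY_Y), pd.DataFrame(TOY_X, columns=["e1", "e2"]))
    assert est.site_scores_.equals(est.site_scores_lc_)
    est_wa = cm.CanonicalCorrespondenceAnalysis(site_score_type="wa")
    est_wa.fit(pd.DataFrame(TOY_Y), pd.DataFrame(TOY_X, columns=["e1", "e2"]))
    assert not est_wa.site_scores_.equals(est.site_scores_lc_)
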