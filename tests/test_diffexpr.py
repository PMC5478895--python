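import numpy as np
import pandas as pd
import pytest

from factoromics.diffexpr import (
    FactorialDE,
    adjust_bh,
    cpm,
    filter_low_counts,
    log_cpm,
    tmm_factors,
    voom_weights,
)


# ---------------------------------------------------------------------------
# CPM filter
# ---------------------------------------------------------------------------


def test_zero_row_removed_and_threshold_semantics():
    # library sizes 1e6 so CPM == count
    counts = pd.DataFrame(
        {
            f"s{j}": [0, 2 if j < 3 else 0, 1]
            for j in range(12)
        },
        index=["zero", "edge", "at_threshold"],
    )
    lib = np.full(12, 1e6)
    kept = filter_low_counts(counts, min_cpm=1, min_libraries=3, lib_sizes=lib)
    assert "zero" not in kept.index
    # CPM 2.0 in exactly 3 libraries: "at least 3 libraries with more than 1 cpm"
    assert "edge" in kept.index
    # CPM exactly 1 is not "more than 1"
    assert "at_threshold" not in kept.index


def test_filter_matches_brute_force_rule():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(0, 40, size=(10, 6)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"s{j}" for j in range(6)],
    )
    lib = counts.sum(axis=0).to_numpy(float)
    kept = set(filter_low_counts(counts, min_cpm=1, min_libraries=3).index)
    expected = set()
    for g in counts.index:
        n_ok = sum(
            counts.loc[g, s] / lib[j] * 1e6 > 1 for j, s in enumerate(counts.columns)
        )
        if n_ok >= 3:
            expected.add(g)
    assert kept == expected


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_oracle(counts: pd.DataFrame, ref: str) -> pd.Series:
    """Straightforward re-implementation of the trim-and-weight definition,
    using sorted-order trimming instead of rank masks."""
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    r = counts.columns.get_loc(ref)
    logf = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == r:
            continue
        ok = (y[:, j] > 0) & (y[:, r] > 0)
        pk, pr = y[ok, j] / lib[j], y[ok, r] / lib[r]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (lib[j] - y[ok, j]) / (lib[j] * y[ok, j]) + (lib[r] - y[ok, r]) / (
            lib[r] * y[ok, r]
        )
        n = m.size
        m_sorted = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        a_sorted = np.argsort(np.argsort(a, kind="stable"), kind="stable")
        keep = (
            (m_sorted + 1 >= np.floor(n * 0.3) + 1)
            & (m_sorted + 1 <= n - np.floor(n * 0.3))
            & (a_sorted + 1 >= np.floor(n * 0.05) + 1)
            & (a_sorted + 1 <= n - np.floor(n * 0.05))
        )
        logf[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return pd.Series(2.0 ** (logf - logf.mean()), index=counts.columns)


def test_identical_libraries_get_unit_factors():
    counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]}, index=list("wxyz"))
    factors = tmm_factors(counts)
    assert np.allclose(factors, 1.0)


def test_pure_depth_difference_is_normalized_away():
    rng = np.random.default_rng(1)
    base = rng.integers(10, 500, 50)
    counts = pd.DataFrame({"a": base, "b": 2 * base}, index=[f"g{i}" for i in range(50)])
    factors = tmm_factors(counts)
    assert np.allclose(factors, 1.0, atol=1e-12)  # pure depth needs no rescaling
    expr = log_cpm(counts, factors)
    # equal up to the 0.5 prior count, whose effect shrinks with the count
    assert np.abs(expr["a"] - expr["b"]).max() < 0.05


def test_tmm_matches_independent_reimplementation():
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.02, size=(20, 3)) + 1,
        index=[f"g{i}" for i in range(20)],
        columns=["a", "b", "c"],
    )
    mine = tmm_factors(counts, ref_sample="a")
    oracle = _tmm_oracle(counts, "a")
    assert np.abs(mine - oracle).max() < 1e-8


def test_all_zero_library_is_an_error():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="no counts"):
        tmm_factors(counts)


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------


def test_log_cpm_closed_form():
    counts = pd.DataFrame({"s": [0]}, index=["g"])
    out = log_cpm(counts, lib_sizes=np.array([1e6]))
    expected = np.log2(0.5 / (1e6 + 1.0) * 1e6)
    assert np.isclose(out.loc["g", "s"], expected)
    assert out.loc["g", "s"] == pytest.approx(-1.0, abs=0.01)


def test_log_cpm_scale_invariance():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(
        rng.integers(100, 1000, size=(5, 3)), index=list("abcde"), columns=list("xyz")
    )
    lib = counts.sum(axis=0).to_numpy(float)
    a = log_cpm(counts, lib_sizes=lib)
    b = log_cpm(2 * counts, lib_sizes=2 * lib)
    # doubling counts and depth together leaves log-CPM essentially unchanged
    # (exactly so up to the fixed 0.5 prior count and +1 offset)
    assert np.abs(a - b).to_numpy().max() < 0.01


def test_voom_weights_track_a_decreasing_variance_trend(tiny_design):
    rng = np.random.default_rng(3)
    X = tiny_design.model_matrix()
    means = np.linspace(2, 12, 120)
    sds = 1.5 / np.sqrt(1 + means)  # decreasing variance with abundance
    Y = means[:, None] + rng.normal(0, sds[:, None], (120, 12))
    expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(120)], columns=tiny_design.sample_ids)
    w = voom_weights(expr, X, lib_sizes=np.full(12, 1e6))
    mean_w = w.mean(axis=1).to_numpy()
    # weights should increase with abundance when the SD trend decreases
    lo = mean_w[means < 5].mean()
    hi = mean_w[means > 9].mean()
    assert hi > lo


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        adj[i] = running
    return adj


def test_bh_small_closed_form():
    assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)


def test_bh_matches_brute_force_step_up():
    rng = np.random.default_rng(4)
    for n in range(1, 11):
        for _ in range(20):
            p = rng.random(n)
            assert np.allclose(adjust_bh(p), _bh_oracle(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_bh([0.1, 1.5])


# ---------------------------------------------------------------------------
# factorial GLM
# ---------------------------------------------------------------------------


def test_constant_feature_has_null_effects(tiny_design):
    expr = pd.DataFrame(
        np.vstack([np.full(12, 7.0), np.random.default_rng(0).normal(5, 1, 12)]),
        index=["flat", "noisy"],
        columns=tiny_design.sample_ids,
    )
    fits = FactorialDE(expr, tiny_design).fit()
    assert np.allclose(fits.coefficients.loc["flat", ["Nlim", "DGA", "DGAxNlim"]], 0.0)
    assert np.allclose(fits.pvalues.loc["flat", ["Nlim", "DGA", "DGAxNlim"]], 1.0)


def test_saturated_cell_means_recovered_exactly(tiny_design):
    a, n, d, i = 5.0, 1.5, -0.75, 2.25
    frame = tiny_design.frame
    values = a + n * frame["nlim"] + d * frame["dga1"] + i * frame["nlim"] * frame["dga1"]
    expr = pd.DataFrame([values.to_numpy()], index=["g"], columns=tiny_design.sample_ids)
    fits = FactorialDE(expr, tiny_design).fit()
    assert np.allclose(fits.coefficients.loc["g"], [a, n, d, i], atol=1e-12)


def test_moderated_t_reduces_to_ordinary_t_without_prior(tiny_design):
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(
        rng.normal(6, 1, size=(40, 12)),
        index=[f"g{i}" for i in range(40)],
        columns=tiny_design.sample_ids,
    )
    model = FactorialDE(expr, tiny_design)
    plain = model.fit(moderate=False)
    assert plain.df_prior == 0.0
    # ordinary t recomputed from scratch
    X = tiny_design.model_matrix().to_numpy()
    XtX_inv = np.linalg.inv(X.T @ X)
    beta, *_ = np.linalg.lstsq(X, expr.to_numpy().T, rcond=None)
    resid = expr.to_numpy() - (X @ beta).T
    s2 = (resid**2).sum(axis=1) / 8
    se = np.sqrt(np.outer(s2, np.diag(XtX_inv)))
    assert np.allclose(plain.tvalues.to_numpy(), beta.T / se, atol=1e-10)


def test_moderation_shrinks_variances_toward_prior(tiny_design):
    rng = np.random.default_rng(6)
    expr = pd.DataFrame(
        rng.normal(6, 1, size=(200, 12)),
        index=[f"g{i}" for i in range(200)],
        columns=tiny_design.sample_ids,
    )
    fits = FactorialDE(expr, tiny_design).fit()
    assert fits.df_prior > 0
    spread_raw = np.log(fits.s2_resid).std()
    spread_post = np.log(fits.s2_post).std()
    assert spread_post < spread_raw


def test_rank_deficient_design_rejected():
    from factoromics.io import StudyDesign

    frame = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "nlim": [0, 0, 0, 1, 1, 1],
            "dga1": [0, 0, 0, 1, 1, 1],  # confounded with nlim
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )
    design = StudyDesign(frame)
    expr = pd.DataFrame(
        np.random.default_rng(7).normal(size=(3, 6)),
        index=list("abc"),
        columns=design.sample_ids,
    )
    with pytest.raises(ValueError, match="rank-deficient"):
        FactorialDE(expr, design)


def test_directional_adjusted_p_magnitude(rna_fits):
    dirp = rna_fits.directional_adj_pvalues
    assert np.allclose(dirp.abs().to_numpy(), rna_fits.adj_pvalues.to_numpy())
    signs = np.sign(rna_fits.coefficients.to_numpy())
    nonzero = signs != 0
    assert np.all(np.sign(dirp.to_numpy())[nonzero] == signs[nonzero])


def test_adjusted_p_dominates_raw_minimum(rna_fits):
    for coef in rna_fits.pvalues.columns:
        assert rna_fits.adj_pvalues[coef].min() >= rna_fits.pvalues[coef].min() - 1e-15
        assert rna_fits.adj_pvalues[coef].between(0, 1).all()


def test_protein_and_metabolite_matrices_reuse_the_same_path(bundle, tiny_design):
    # the identical class accepts any log-scale feature matrix
    mets = np.log2(bundle.metabolites)
    fits = FactorialDE.from_dataframe(mets, bundle.design).fit()
    assert list(fits.coefficients.columns) == ["Intercept", "Nlim", "DGA", "DGAxNlim"]
    # planted IPM-like interaction effect is negative and significant
    assert fits.coefficients.loc["2-isopropylmalate", "DGAxNlim"] < -1
    assert fits.adj_pvalues.loc["2-isopropylmalate", "DGAxNlim"] < 0.05
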