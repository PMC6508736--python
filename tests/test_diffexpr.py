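"""Dispersion estimation, the conditional NB exact test, BH FDR, t-tests
and ratio-of-means reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest, nbinom, t as t_dist

import sertoli_sig as ss
from sertoli_sig.diffexpr import (
    bh_fdr,
    equalized_pseudocounts,
    estimate_dispersion,
    ma_volcano_tables,
    nb_exact_pvalue,
)
from sertoli_sig.normalization import ExpressionMatrix


# ---------------------------------------------------------------- dispersion


def _pseudo(rows, samples=None):
    arr = np.atleast_2d(np.asarray(rows))
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"G{i}" for i in range(arr.shape[0])],
                        columns=samples)


def test_dispersion_moment_examples():
    groups = pd.Series(["CS", "CS"], index=["s0", "s1"])
    flat = estimate_dispersion(_pseudo([[10, 10]]), groups)
    assert flat.loc["G0", "phi_raw"] == 0.0
    # mu=10, s2=50 -> (50-10)/100 = 0.4 before shrinkage
    spread = estimate_dispersion(_pseudo([[5, 15]]), groups)
    assert np.isclose(spread.loc["G0", "phi_raw"], 0.4)
    # all-zero gene -> phi 0
    zero = estimate_dispersion(_pseudo([[0, 0]]), groups)
    assert zero.loc["G0", "phi"] == 0.0


def test_dispersion_poisson_simulation_is_small():
    """On Poisson data (true phi = 0) the median estimate stays near zero."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(100.0, size=(1000, 11))
    groups = pd.Series(["CS"] * 4 + ["SCO"] * 7, index=[f"s{i}" for i in range(11)])
    est = estimate_dispersion(_pseudo(counts), groups)
    assert est["phi"].median() <= 0.05


def test_dispersion_requires_replication():
    groups = pd.Series(["CS", "SCO"], index=["s0", "s1"])
    with pytest.raises(ValueError, match="fewer than 2"):
        estimate_dispersion(_pseudo([[1, 2]]), groups)


# ---------------------------------------------------------------- exact test


def _oracle_pvalue(s_obs, T, n1, n2, phi):
    """Brute-force conditional enumeration using scipy nbinom/poisson pmf
    products — an independent route to the same conditional law."""
    from scipy.stats import poisson

    if T == 0:
        return 1.0
    probs = np.empty(T + 1)
    for s in range(T + 1):
        if phi == 0:
            probs[s] = poisson.pmf(s, n1) * poisson.pmf(T - s, n2)
        else:
            r1, r2 = n1 / phi, n2 / phi
            probs[s] = nbinom.pmf(s, r1, r1 / (r1 + n1)) * nbinom.pmf(
                T - s, r2, r2 / (r2 + n2)
            )
    probs /= probs.sum()
    return min(1.0, probs[probs <= probs[s_obs] * (1 + 1e-7)].sum())


def test_exact_test_symmetric_mode_gives_p_one():
    # equal groups, observed split at the conditional mode
    assert nb_exact_pvalue(5, 10, 3, 3, 0.0) == 1.0
    assert nb_exact_pvalue(3, 6, 2, 2, 0.5) == 1.0


def test_exact_test_zero_total_convention():
    assert nb_exact_pvalue(0, 0, 4, 7, 0.3) == 1.0


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
@pytest.mark.parametrize("n1,n2", [(4, 7), (3, 3)])
def test_exact_test_matches_enumeration_oracle(phi, n1, n2):
    for T in range(0, 31):
        for s in range(T + 1):
            p = nb_exact_pvalue(s, T, n1, n2, phi)
            assert p == pytest.approx(_oracle_pvalue(s, T, n1, n2, phi), abs=1e-10)


def test_exact_test_phi_zero_equals_binomial_test():
    for T in range(1, 31):
        for s in range(T + 1):
            expected = binomtest(s, T, 4 / 11).pvalue
            assert nb_exact_pvalue(s, T, 4, 7, 0.0) == pytest.approx(expected, abs=1e-12)


def test_exact_test_phi_half_t6_brute_force():
    for s in range(7):
        assert nb_exact_pvalue(s, 6, 4, 7, 0.5) == pytest.approx(
            _oracle_pvalue(s, 6, 4, 7, 0.5), abs=1e-12
        )


def test_equalized_pseudocounts_common_size():
    counts = pd.DataFrame(
        {"a": [100, 300], "b": [50, 150]}, index=["G0", "G1"]
    )
    cm = ss.CountMatrix.from_counts(counts)
    pseudo = equalized_pseudocounts(cm)
    # common size = sqrt(400 * 200); column sums equalized up to rounding
    assert np.allclose(pseudo.sum(axis=0), np.sqrt(400 * 200), atol=1.0)


def test_nb_exact_test_table_contract(default_cohort, groups, cfg):
    cm, _, _ = default_cohort
    sub = ss.CountMatrix.from_counts(cm.counts.iloc[:40], cm.library_sizes)
    de = ss.nb_exact_test(sub, groups, cfg)
    assert ((de["p_value"] >= 0) & (de["p_value"] <= 1)).all()
    assert ((de["fdr"] >= 0) & (de["fdr"] <= 1)).all()
    # direction is ns exactly when FDR fails the cutoff
    assert ((de["direction"] == "ns") == (de["fdr"] >= cfg.fdr_max)).all()


# ---------------------------------------------------------------- BH FDR


def _bh_oracle(p):
    """Literal step-up definition: q_i = min_{j: p_(j) >= p_(i)} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, i in enumerate(order):
        candidates = [
            m * p[j] / (rank_j + 1)
            for rank_j, j in enumerate(order)
            if rank_j >= rank_i
        ]
        q[i] = min(1.0, min(candidates))
    return q


def test_bh_fdr_examples():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_fdr_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_bh_fdr_matches_stepup_oracle_on_random_vectors():
    rng = np.random.default_rng(7)
    for _ in range(300):
        m = int(rng.integers(1, 30))
        p = rng.random(m)
        assert bh_fdr(p) == pytest.approx(_bh_oracle(p), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_fdr_monotone_in_sorted_p(p):
    q = bh_fdr(p)
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------- t-tests


def _actin_em(cs, sco):
    arr = np.atleast_2d(np.concatenate([cs, sco], axis=-1))
    cols = [f"c{i}" for i in range(np.shape(cs)[-1])] + [
        f"x{i}" for i in range(np.shape(sco)[-1])
    ]
    values = pd.DataFrame(arr, index=[f"G{i}" for i in range(arr.shape[0])],
                          columns=cols)
    groups = pd.Series(
        ["CS"] * np.shape(cs)[-1] + ["SCO"] * np.shape(sco)[-1], index=cols
    )
    return ExpressionMatrix(values=values, state="actin_ratio"), groups


def test_ttest_identical_groups(cfg):
    em, groups = _actin_em([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    out = ss.group_ttest(em, groups, cfg)
    assert out.loc[0, "t_stat"] == 0.0 and out.loc[0, "p_value"] == 1.0


def test_ttest_degenerate_zero_variance(cfg):
    em, groups = _actin_em([2.0, 2.0], [2.0, 2.0])
    out = ss.group_ttest(em, groups, cfg)
    assert out.loc[0, "p_value"] == 1.0 and out.loc[0, "t_stat"] == 0.0


def test_ttest_label_swap_symmetry(cfg):
    em, groups = _actin_em([1.0, 2.5, 3.0], [4.0, 5.5, 6.0, 7.0])
    out = ss.group_ttest(em, groups, cfg)
    swapped = groups.map({"CS": "SCO", "SCO": "CS"})
    out_sw = ss.group_ttest(em, swapped, cfg)
    assert out_sw.loc[0, "p_value"] == pytest.approx(out.loc[0, "p_value"])
    assert out_sw.loc[0, "t_stat"] == pytest.approx(-out.loc[0, "t_stat"])


def test_ttest_closed_form(cfg):
    """CS=[1,2,3] vs SCO=[4,5,6]: equal variances, so the Welch statistic
    equals the pooled Student one and the Welch df reduce to 4."""
    em, groups = _actin_em([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    out = ss.group_ttest(em, groups, cfg)
    t_expected = (2.0 - 5.0) / np.sqrt(1.0 / 3 + 1.0 / 3)
    p_expected = 2 * t_dist.sf(abs(t_expected), 4)
    assert out.loc[0, "t_stat"] == pytest.approx(t_expected)
    assert out.loc[0, "p_value"] == pytest.approx(p_expected)
    # pooled-variance mode agrees here too (equal n, equal variance)
    out_student = ss.group_ttest(em, groups, cfg, welch=False)
    assert out_student.loc[0, "p_value"] == pytest.approx(p_expected)


def test_ttest_significance_is_inclusive():
    em, groups = _actin_em([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    out = ss.group_ttest(em, groups, ss.ThresholdConfig())
    p = float(out.loc[0, "p_value"])
    cfg_at = ss.ThresholdConfig(ttest_alpha=p)  # alpha exactly at p
    out_at = ss.group_ttest(em, groups, cfg_at)
    assert bool(out_at.loc[0, "significant"])


# ---------------------------------------------------------------- ratios & MA


def test_ratio_percent_examples():
    de = pd.DataFrame(
        {"gene_id": ["A", "B", "C"], "mean_cs": [25.0, 4.0, 0.0],
         "mean_sco": [2.0, 4.0, 9.0]}
    )
    out = ss.ratio_percent(de)
    assert out["percent_of_cs"].tolist()[:2] == [8.0, 100.0]
    assert np.isnan(out["percent_of_cs"].iloc[2])


def test_ratio_percent_scale_invariance():
    rng = np.random.default_rng(11)
    cs, sco = rng.random(20) + 0.1, rng.random(20) + 0.1
    de = pd.DataFrame({"gene_id": range(20), "mean_cs": cs, "mean_sco": sco})
    de_scaled = de.assign(mean_cs=cs * 37.5, mean_sco=sco * 37.5)
    assert ss.ratio_percent(de)["percent_of_cs"].values == pytest.approx(
        ss.ratio_percent(de_scaled)["percent_of_cs"].values
    )


def test_ma_volcano_tables():
    empty_ma, empty_v = ma_volcano_tables(pd.DataFrame())
    assert empty_ma.empty and empty_v.empty

    de = pd.DataFrame(
        {
            "gene_id": ["A", "B", "C"],
            "mean_cs": [100.0, 0.1, 50.0],
            "mean_sco": [110.0, 0.0, 60.0],
            "log_fc": [0.13, -6.0, 0.26],
            "p_value": [0.5, 0.001, 0.4],
            "fdr": [0.6, 0.01, 0.5],
        }
    )
    ma, volcano = ma_volcano_tables(de)
    assert ma["low_expression_outlier"].sum() == 1
    assert ma.loc[ma["low_expression_outlier"], "gene_id"].tolist() == ["B"]
    assert len(volcano) == 3
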