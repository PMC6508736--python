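"""Two-group differential expression.

Count data are compared with a conditional negative-binomial exact test on
library-size-equalized pseudo-counts, with Benjamini-Hochberg control of the
false discovery rate.  Beta-actin-normalized expression ratios are compared
with two-tailed t-tests (Welch by default).

The exact test conditions on the total pseudo-count T of a gene.  If the
counts in each sample are i.i.d. NB(mean mu, variance mu + phi*mu^2), the
group sums are NB with sizes r1 = n1/phi and r2 = n2/phi, and given
S1 + S2 = T the group-1 sum follows the Polya (Dirichlet-multinomial)
law

    P(S1 = s | T) = C(s + r1 - 1, s) * C(T - s + r2 - 1, T - s)
                    / C(T + r1 + r2 - 1, T),

which degenerates to Binomial(T, n1/(n1+n2)) as phi -> 0.  The two-sided
p-value is the total conditional probability of splits no more probable
than the observed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom, t as t_dist
from statsmodels.stats.multitest import multipletests

from .data_io import CountMatrix, ThresholdConfig, logger
from .normalization import ExpressionMatrix

#: Relative tolerance used when comparing split probabilities to the
#: observed one, so that floating-point ties count as ties.
_PROB_RTOL = 1e-7


# ---------------------------------------------------------------------------
# Library-size equalization and dispersion
# ---------------------------------------------------------------------------


def equalized_pseudocounts(
    cm: CountMatrix, tmm: pd.Series | None = None
) -> pd.DataFrame:
    """Rescale counts to a common effective library size.

    The common size is the geometric mean of the TMM-corrected effective
    library sizes; rescaled values are rounded half-to-even so the exact
    test sees exchangeable integer totals.
    """
    eff = cm.library_sizes.astype(float)
    if tmm is not None:
        eff = eff * tmm.reindex(eff.index)
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(cm.counts.to_numpy(float) * (common / eff.to_numpy())[None, :])
    return pd.DataFrame(pseudo.astype(np.int64), index=cm.counts.index,
                        columns=cm.counts.columns)


def estimate_dispersion(
    pseudo: pd.DataFrame,
    groups: pd.Series,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Method-of-moments NB dispersion per gene with shrinkage to the median.

    Within-group means and a pooled within-group variance give the raw
    moments estimate ``phi_raw = max(0, (s^2 - mu) / mu^2)``; each gene's
    estimate is then averaged with the common (median) value using weight
    ``shrink_weight`` to stabilize the small-sample noise of the per-gene
    moments.  All-zero genes get phi = 0.
    """
    groups = groups.reindex(pseudo.columns)
    labels = groups.unique()
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    x = pseudo.to_numpy(float)
    mu = x.mean(axis=1)
    ss = np.zeros(len(pseudo))
    for lab in labels:
        cols = (groups == lab).to_numpy()
        xg = x[:, cols]
        ss += ((xg - xg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = x.shape[1] - len(labels)
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), 0.0)
    expressed = mu > 0
    common = float(np.median(phi_raw[expressed])) if expressed.any() else 0.0
    phi = (1.0 - shrink_weight) * phi_raw + shrink_weight * common
    phi[~expressed] = 0.0
    return pd.DataFrame(
        {
            "gene_id": pseudo.index,
            "phi_raw": phi_raw,
            "phi": phi,
            "method": np.where(expressed, "moments_shrunk", "moments"),
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Conditional NB exact test
# ---------------------------------------------------------------------------


def _conditional_logpmf(T: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Log pmf of the group-1 sum over its full support 0..T given the total."""
    s = np.arange(T + 1)
    if phi <= 0:
        return binom.logpmf(s, T, n1 / (n1 + n2))
    r1, r2 = n1 / phi, n2 / phi
    logw = (
        gammaln(s + r1)
        - gammaln(s + 1)
        - gammaln(r1)
        + gammaln(T - s + r2)
        - gammaln(T - s + 1)
        - gammaln(r2)
    )
    # closed-form normalizer: NB(r1) + NB(r2) = NB(r1 + r2)
    logz = gammaln(T + r1 + r2) - gammaln(T + 1) - gammaln(r1 + r2)
    return logw - logz


def nb_exact_pvalue(s1: int, T: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact p-value for the observed group-1 total ``s1``."""
    if T == 0:
        return 1.0
    logpmf = _conditional_logpmf(T, n1, n2, phi)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    thresh = pmf[s1] * (1.0 + _PROB_RTOL)
    return float(min(1.0, pmf[pmf <= thresh].sum()))


def nb_exact_test(
    cm: CountMatrix,
    groups: pd.Series,
    cfg: ThresholdConfig,
    dispersion: pd.DataFrame | None = None,
    tmm: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene conditional NB exact test of CS vs SCO counts.

    Returns a DataFrame with group mean CPMs, log2 fold change
    (SCO over CS, with ``cfg.log_prior`` added to each mean), exact
    p-values, BH FDR and a direction call (``ns`` unless FDR < fdr_max).
    """
    groups = groups.reindex(cm.counts.columns)
    if set(groups.unique()) != {"CS", "SCO"}:
        raise ValueError("nb_exact_test expects exactly the groups CS and SCO")
    pseudo = equalized_pseudocounts(cm, tmm)
    if dispersion is None:
        dispersion = estimate_dispersion(pseudo, groups)
    phi = dispersion["phi"].reindex(pseudo.index).to_numpy()

    cs_cols = (groups == "CS").to_numpy()
    sco_cols = (groups == "SCO").to_numpy()
    n_cs, n_sco = int(cs_cols.sum()), int(sco_cols.sum())
    s_cs = pseudo.to_numpy()[:, cs_cols].sum(axis=1)
    s_sco = pseudo.to_numpy()[:, sco_cols].sum(axis=1)

    pvals = np.ones(len(pseudo))
    for i in range(len(pseudo)):
        T = int(s_cs[i] + s_sco[i])
        pvals[i] = nb_exact_pvalue(int(s_cs[i]), T, n_cs, n_sco, float(phi[i]))

    eff = cm.library_sizes.astype(float)
    if tmm is not None:
        eff = eff * tmm.reindex(eff.index)
    cpm = cm.counts.div(eff, axis=1) * 1e6
    mean_cs = cpm.loc[:, cs_cols].mean(axis=1).to_numpy()
    mean_sco = cpm.loc[:, sco_cols].mean(axis=1).to_numpy()
    log_fc = np.log2((mean_sco + cfg.log_prior) / (mean_cs + cfg.log_prior))

    fdr = bh_fdr(pvals)
    direction = np.where(
        fdr < cfg.fdr_max, np.where(mean_sco >= mean_cs, "up_in_sco", "down_in_sco"), "ns"
    )
    out = pd.DataFrame(
        {
            "gene_id": pseudo.index,
            "mean_cs": mean_cs,
            "mean_sco": mean_sco,
            "log_fc": log_fc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    )
    logger.info(
        "NB exact test: %d genes, %d significant at FDR<%.3g",
        len(out), int((fdr < cfg.fdr_max).sum()), cfg.fdr_max,
    )
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Actin-ratio t-tests and ratio-of-means reporting
# ---------------------------------------------------------------------------


def group_ttest(
    em: ExpressionMatrix,
    groups: pd.Series,
    cfg: ThresholdConfig,
    welch: bool = True,
) -> pd.DataFrame:
    """Two-tailed two-sample t-test per gene on actin-normalized values.

    Welch (unequal variance) by default; ``welch=False`` selects the pooled
    variance Student test.  Significance is inclusive at p <= ttest_alpha.
    Degenerate genes with zero variance in both groups get t = 0, p = 1 when
    the means agree and p = 0 otherwise.
    """
    if em.state != "actin_ratio":
        raise ValueError("group_ttest expects actin-ratio values")
    groups = groups.reindex(em.values.columns)
    cs = em.values.loc[:, (groups == "CS").to_numpy()].to_numpy(float)
    sco = em.values.loc[:, (groups == "SCO").to_numpy()].to_numpy(float)
    if cs.shape[1] < 2 or sco.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    n1, n2 = cs.shape[1], sco.shape[1]
    m1, m2 = cs.mean(axis=1), sco.mean(axis=1)
    v1 = cs.var(axis=1, ddof=1)
    v2 = sco.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1 / n1 + 1 / n2)
            df = np.full(len(m1), n1 + n2 - 2, dtype=float)
        tstat = (m1 - m2) / np.sqrt(se2)
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df)
    degenerate = se2 == 0
    equal_means = degenerate & np.isclose(m1, m2)
    tstat[equal_means] = 0.0
    pvals[equal_means] = 1.0
    pvals[degenerate & ~equal_means] = 0.0
    tstat[degenerate & ~equal_means] = np.sign(m1 - m2)[degenerate & ~equal_means] * np.inf
    significant = pvals <= cfg.ttest_alpha
    return pd.DataFrame(
        {
            "gene_id": em.values.index,
            "mean_cs": m1,
            "mean_sco": m2,
            "t_stat": tstat,
            "p_value": pvals,
            "significant": significant,
            "direction": np.where(
                significant, np.where(m2 >= m1, "up_in_sco", "down_in_sco"), "ns"
            ),
        }
    )


def ratio_percent(de: pd.DataFrame) -> pd.DataFrame:
    """Add ``percent_of_cs`` = 100 * mean_sco / mean_cs (NaN when mean_cs is 0)."""
    out = de.copy()
    mean_cs = out["mean_cs"].to_numpy(float)
    mean_sco = out["mean_sco"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(mean_cs > 0, 100.0 * mean_sco / mean_cs, np.nan)
    n_missing = int(np.isnan(pct).sum())
    if n_missing:
        logger.info("percent_of_cs undefined for %d genes with zero CS mean", n_missing)
    out["percent_of_cs"] = pct
    return out


def ma_volcano_tables(
    de: pd.DataFrame, log_prior: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format MA and volcano diagnostic tables.

    The MA table flags |logFC| > 5 genes with mean CPM < 1 as low-expression
    outliers; an over-abundance of such genes would indicate that the
    expression filter threshold is too permissive.
    """
    if de.empty:
        cols_ma = ["gene_id", "a_value", "log_fc", "low_expression_outlier"]
        cols_v = ["gene_id", "log_fc", "neg_log10_fdr"]
        return pd.DataFrame(columns=cols_ma), pd.DataFrame(columns=cols_v)
    mean_cpm = (de["mean_cs"].to_numpy(float) + de["mean_sco"].to_numpy(float)) / 2.0
    a_value = np.log2(mean_cpm + log_prior)
    log_fc = de["log_fc"].to_numpy(float)
    outlier = (np.abs(log_fc) > 5) & (mean_cpm < 1)
    ma = pd.DataFrame(
        {
            "gene_id": de["gene_id"],
            "a_value": a_value,
            "log_fc": log_fc,
            "low_expression_outlier": outlier,
        }
    )
    q = de["fdr"] if "fdr" in de.columns else de["p_value"]
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(np.maximum(q.to_numpy(float), np.finfo(float).tiny))
    volcano = pd.DataFrame(
        {"gene_id": de["gene_id"], "log_fc": log_fc, "neg_log10_fdr": neg_log10}
    )
    return ma, volcano
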