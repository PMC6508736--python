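"""Expression normalization: CPM, expression filtering, TMM, log2, actin
ratios and the signature-panel median rescaling.

State machine for :class:`ExpressionMatrix`:

    raw_cpm -> tmm_cpm -> log2
    raw_cpm -> actin_ratio
    tmm_cpm -> median_scaled
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import CountMatrix, ThresholdConfig, canonical_symbols, logger

STATES = ("raw_cpm", "tmm_cpm", "log2", "actin_ratio", "median_scaled")

_ALLOWED_TRANSITIONS = {
    ("raw_cpm", "tmm_cpm"),
    ("tmm_cpm", "log2"),
    ("raw_cpm", "actin_ratio"),
    ("tmm_cpm", "median_scaled"),
    # re-applying the median rescaling is legal (and a no-op)
    ("median_scaled", "median_scaled"),
}


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression with a processing-state tag."""

    values: pd.DataFrame
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        arr = self.values.to_numpy(float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")

    def _check_transition(self, target: str) -> None:
        if (self.state, target) not in _ALLOWED_TRANSITIONS:
            raise ValueError(f"invalid state transition {self.state} -> {target}")


def compute_cpm(cm: CountMatrix) -> ExpressionMatrix:
    """Counts per million mapped reads: counts / library_size * 1e6."""
    lib = cm.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero or negative library size for samples {bad}")
    values = cm.counts.div(lib, axis=1) * 1e6
    return ExpressionMatrix(values=values, state="raw_cpm")


def filter_expressed(
    em: ExpressionMatrix,
    cs_sample_ids: Sequence[str],
    cfg: ThresholdConfig,
    gene_biotype: pd.Series | None = None,
    mrna_biotypes: frozenset[str] = frozenset({"protein_coding"}),
) -> list[str]:
    """Genes expressed above ``cpm_min`` (strict) in >= ``min_cs_libraries``
    complete-spermatogenesis libraries.

    Genes whose biotype marks them as not mRNA-encoding are purged first;
    when no biotype annotation is available the purge is a no-op.
    """
    if em.state != "raw_cpm":
        raise ValueError("expression filter operates on raw CPM values")
    cs_sample_ids = list(cs_sample_ids)
    if not cs_sample_ids:
        raise ValueError("no CS samples given")
    if len(cs_sample_ids) < cfg.min_cs_libraries:
        raise ValueError(
            f"only {len(cs_sample_ids)} CS samples but min_cs_libraries="
            f"{cfg.min_cs_libraries}"
        )
    values = em.values
    if gene_biotype is not None:
        keep_bt = gene_biotype.reindex(values.index).isin(mrna_biotypes)
        n_purged = int((~keep_bt).sum())
        if n_purged:
            logger.info("purged %d genes with non-mRNA biotype", n_purged)
        values = values.loc[keep_bt]
    n_pass = (values[cs_sample_ids] > cfg.cpm_min).sum(axis=1)
    retained = values.index[n_pass >= cfg.min_cs_libraries].tolist()
    logger.info("expression filter retained %d / %d genes", len(retained), len(em.values))
    return retained


# ---------------------------------------------------------------------------
# TMM (trimmed mean of M-values) scaling factors
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor for one sample against the reference sample.

    M-values (log ratios) are trimmed by ``trim_m`` on each tail and
    A-values (log abundance) by ``trim_a``; the surviving M-values are
    combined by a precision-weighted mean using the asymptotic binomial
    variance of each log ratio.
    """
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise ValueError("sample shares no co-expressed genes with the reference")
    o, r = obs[mask], ref[mask]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-10:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / var[keep]
    return float(2 ** (np.sum(w * m[keep]) / np.sum(w)))


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    When ``ref_sample`` is not given, the reference is the sample whose
    upper-quartile CPM is closest to the mean upper quartile.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = cm.counts.to_numpy(float)
    lib = cm.library_sizes.to_numpy(float)
    cpm = counts / lib * 1e6
    samples = list(cm.counts.columns)
    if ref_sample is None:
        uq = np.quantile(cpm, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in samples:
            raise ValueError(f"unknown reference sample {ref_sample!r}")
        ref_idx = samples.index(ref_sample)
    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def tmm_cpm(cm: CountMatrix, factors: pd.Series | None = None) -> ExpressionMatrix:
    """CPM on TMM-corrected effective library sizes."""
    if factors is None:
        factors = tmm_factors(cm)
    eff = cm.library_sizes * factors.reindex(cm.library_sizes.index)
    values = cm.counts.div(eff, axis=1) * 1e6
    return ExpressionMatrix(values=values, state="tmm_cpm")


def log2_transform(em: ExpressionMatrix, prior: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + prior)."""
    em._check_transition("log2")
    if prior < 0:
        raise ValueError("log2 prior must be >= 0")
    if (em.values.to_numpy() < 0).any():
        raise ValueError("log2 transform requires non-negative values")
    return ExpressionMatrix(values=np.log2(em.values + prior), state="log2")


def actin_normalize(em: ExpressionMatrix, actin_gene: str = "ACTB") -> ExpressionMatrix:
    """Divide every gene's CPM by the beta-actin CPM of the same sample.

    Useful when overall cellularity differs between groups (somatic
    transcripts, beta actin included, are globally enriched in germ
    cell-depleted testes); ratios to a stably expressed somatic transcript
    put the two groups on a comparable per-somatic-cell scale.
    """
    em._check_transition("actin_ratio")
    actin_gene = canonical_symbols([actin_gene])[0]
    if actin_gene not in em.values.index:
        raise ValueError(f"actin gene {actin_gene!r} absent from expression matrix")
    actin = em.values.loc[actin_gene]
    if (actin <= 0).any():
        bad = actin.index[actin <= 0].tolist()
        raise ValueError(f"{actin_gene} CPM is zero in samples {bad}")
    return ExpressionMatrix(values=em.values.div(actin, axis=1), state="actin_ratio")


def median_scale_signature(
    em: ExpressionMatrix, signature_genes: Sequence[str]
) -> ExpressionMatrix:
    """Rescale each sample so the signature-panel medians are identical.

    Each sample's signature CPMs are multiplied by target/sample median,
    where the target is the median of the per-sample medians.  Idempotent.
    """
    em._check_transition("median_scaled")
    genes = [g for g in canonical_symbols(signature_genes) if g in em.values.index]
    if len(genes) < 3:
        raise ValueError("need at least 3 signature genes present for median scaling")
    panel = em.values.loc[genes]
    if panel.shape[1] == 1:
        return ExpressionMatrix(values=panel.copy(), state="median_scaled")
    sample_medians = panel.median(axis=0)
    if (sample_medians <= 0).any():
        bad = sample_medians.index[sample_medians <= 0].tolist()
        raise ValueError(f"zero signature-panel median in samples {bad}")
    target = float(sample_medians.median())
    scaled = panel.mul(target / sample_medians, axis=1)
    return ExpressionMatrix(values=scaled, state="median_scaled")
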