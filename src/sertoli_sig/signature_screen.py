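"""The two-step Sertoli cell signature screen.

Step 1 exploits the conservation of Sertoli cell function across mammals:
transcripts at least ``rat_fold`` higher in rat Sertoli cells than in every
other rat testicular cell type (Leydig, spermatogonia, pachytene
spermatocytes, round spermatids) are candidate Sertoli transcripts, mapped
to human symbols through a one-to-one ortholog table and optionally
augmented with a manually curated list.

Step 2 estimates, for each candidate, the amount contributed by Sertoli
cells to the bulk testis transcriptome by subtraction: total testis CPM
minus the composition-weighted contributions of Leydig and germ cell types
(whose per-cell transcriptomes are known).  A transcript is called a
signature transcript when

    (a) Sertoli cells supply at least 60% of the testis total,
    (b) per-cell Sertoli expression is at least twice the Leydig level, and
    (c) per-cell Sertoli expression exceeds every germ cell type (strict).

Criterion (a) is a share of the testis total; (b) and (c) compare per-cell
expression levels (the subtraction estimate divided by the Sertoli mRNA
fraction, against the per-cell reference columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ThresholdConfig, canonical_symbols, logger

RAT5_CELL_TYPES = (
    "Sertoli",
    "Leydig",
    "spermatogonia",
    "pachytene_spermatocytes",
    "round_spermatids",
)

SERTOLI = "Sertoli"
LEYDIG = "Leydig"

COLUMN_SCALE = 1e6  # reference columns are rescaled to CPM-like units


@dataclass
class CellTypeReference:
    """Per-cell-type relative expression profiles (genes x cell types).

    Columns are rescaled to sum to 1e6 so that composition fractions are
    interpretable as mRNA-mass fractions and per-cell columns share units
    with bulk CPM.
    """

    panel_id: str
    expr: pd.DataFrame

    def __post_init__(self) -> None:
        self.expr = self.expr.copy()
        self.expr.index = pd.Index(canonical_symbols(self.expr.index), name="gene_id")
        arr = self.expr.to_numpy(float)
        if (arr < 0).any():
            raise ValueError("reference expression must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.expr.columns)

    def rescaled(self) -> "CellTypeReference":
        """Each column rescaled to sum to 1e6."""
        sums = self.expr.sum(axis=0)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0].tolist()
            raise ValueError(f"all-zero reference columns: {bad}")
        return CellTypeReference(
            panel_id=self.panel_id, expr=self.expr * (COLUMN_SCALE / sums)
        )

    def is_rescaled(self, tol: float = 1e-6) -> bool:
        return bool(np.allclose(self.expr.sum(axis=0), COLUMN_SCALE, atol=tol))


@dataclass
class CellComposition:
    """Relative cell numbers n_k and per-cell mRNA content s_k.

    The mRNA-mass fraction of cell type k is f_k = n_k s_k / sum_j n_j s_j.
    mRNA content defaults to 1 (equal transcript mass per cell).
    """

    weights: pd.Series
    mrna_content: pd.Series | None = None

    def __post_init__(self) -> None:
        self.weights = self.weights.astype(float)
        if (self.weights < 0).any():
            bad = self.weights.index[self.weights < 0].tolist()
            raise ValueError(f"negative composition weights for {bad}")
        if self.mrna_content is None:
            self.mrna_content = pd.Series(1.0, index=self.weights.index)
        self.mrna_content = self.mrna_content.reindex(self.weights.index).astype(float)
        if (self.mrna_content <= 0).any() or self.mrna_content.isna().any():
            raise ValueError("mRNA content must be positive for every cell type")

    @property
    def fractions(self) -> pd.Series:
        mass = self.weights * self.mrna_content
        total = mass.sum()
        if total <= 0:
            raise ValueError("composition weights sum to zero")
        return mass / total

    @property
    def cell_types(self) -> list[str]:
        return list(self.weights.index)


# ---------------------------------------------------------------------------
# Step 1: cross-species candidate screen
# ---------------------------------------------------------------------------


def rat_screen(ref: CellTypeReference, fold: float = 4.0) -> list[str]:
    """Transcripts at least ``fold`` higher in rat Sertoli cells than in
    every other cell type of the 5-cell-type rat panel.

    The comparison is inclusive (>=).  Genes whose non-Sertoli expression is
    all zero are kept iff the Sertoli value is positive.
    """
    if SERTOLI not in ref.expr.columns:
        raise ValueError("rat reference lacks a Sertoli column")
    sertoli = ref.expr[SERTOLI].to_numpy(float)
    others = ref.expr.drop(columns=[SERTOLI]).to_numpy(float)
    keep = (sertoli > 0) & (sertoli[:, None] >= fold * others).all(axis=1)
    kept = ref.expr.index[keep].tolist()
    logger.info("rat screen kept %d / %d genes at fold >= %g", len(kept), len(ref.expr), fold)
    return kept


def map_orthologs(
    candidates: Sequence[str], orthologs: pd.DataFrame
) -> tuple[list[str], pd.DataFrame]:
    """Map rat candidates to human symbols through one-to-one orthology.

    Returns the mapped human list (first-seen order) and a per-candidate
    report with status ``mapped`` / ``unmapped`` / ``multi``.
    """
    candidates = canonical_symbols(candidates)
    by_rat: dict[str, list[str]] = {}
    multi_flag: dict[str, bool] = {}
    for _, row in orthologs.iterrows():
        by_rat.setdefault(row["rat_gene"], []).append(row["human_gene"])
        if bool(row.get("multi_mapping", False)):
            multi_flag[row["rat_gene"]] = True
    mapped: list[str] = []
    report_rows = []
    for rat_gene in candidates:
        targets = sorted(set(by_rat.get(rat_gene, [])))
        if not targets:
            report_rows.append((rat_gene, "", "unmapped"))
        elif len(targets) > 1 or multi_flag.get(rat_gene, False):
            report_rows.append((rat_gene, ";".join(targets), "multi"))
        else:
            human = targets[0]
            report_rows.append((rat_gene, human, "mapped"))
            if human not in mapped:
                mapped.append(human)
    report = pd.DataFrame(report_rows, columns=["rat_gene", "human_gene", "status"])
    logger.info(
        "ortholog mapping: %d mapped, %d unmapped, %d multi",
        (report["status"] == "mapped").sum(),
        (report["status"] == "unmapped").sum(),
        (report["status"] == "multi").sum(),
    )
    return mapped, report


def augment_candidates(
    mapped: Sequence[str], manual: Sequence[str] | None = None
) -> list[str]:
    """Union of screen output and a manually curated augmentation list,
    preserving first-seen order; duplicates are logged, not an error."""
    manual = manual or []
    seen: set[str] = set()
    out: list[str] = []
    dups: list[str] = []
    for sym in canonical_symbols(list(mapped) + list(manual)):
        if sym in seen:
            dups.append(sym)
        else:
            seen.add(sym)
            out.append(sym)
    if dups:
        logger.info("augmentation list overlapped screen output for %d symbols", len(dups))
    return out


# ---------------------------------------------------------------------------
# Step 2: subtraction deconvolution and signature calls
# ---------------------------------------------------------------------------


def estimate_sertoli(
    total_cpm: pd.Series,
    ref: CellTypeReference,
    comp: CellComposition,
) -> pd.DataFrame:
    """Estimate the Sertoli contribution to each transcript by subtraction.

    ``total_cpm`` is the mean CS-testis CPM per gene.  The non-Sertoli
    contribution is sum over measured cell types of f_k * E_k(g) with E_k
    the per-cell reference columns (rescaled to 1e6); the Sertoli amount is
    the floored difference, its share of the total the Sertoli fraction, and
    dividing by f_Sertoli gives a per-cell expression estimate.

    Genes absent from the reference are treated as zero non-Sertoli
    contribution and flagged ``in_reference=False``.
    """
    fractions = comp.fractions
    if SERTOLI not in fractions.index or fractions[SERTOLI] <= 0:
        raise ValueError("composition must include Sertoli cells with positive fraction")
    f_sertoli = float(fractions[SERTOLI])
    if not ref.is_rescaled():
        ref = ref.rescaled()
    non_sertoli_types = [c for c in ref.expr.columns if c != SERTOLI]
    missing_fraction = [c for c in non_sertoli_types if c not in fractions.index]
    if missing_fraction:
        raise ValueError(f"composition lacks weights for cell types {missing_fraction}")

    total_cpm = total_cpm.copy()
    total_cpm.index = pd.Index(canonical_symbols(total_cpm.index), name="gene_id")
    expr = ref.expr.reindex(total_cpm.index)
    in_reference = ~expr.isna().all(axis=1)
    expr = expr.fillna(0.0)
    weights = fractions[non_sertoli_types].to_numpy()
    nonsertoli = expr[non_sertoli_types].to_numpy() @ weights
    total = total_cpm.to_numpy(float)
    amount = np.maximum(0.0, total - nonsertoli)
    with np.errstate(divide="ignore", invalid="ignore"):
        fraction = np.where(total > 0, amount / total, 0.0)
    out = pd.DataFrame(
        {
            "gene_id": total_cpm.index,
            "total_cpm": total,
            "nonsertoli_contribution": nonsertoli,
            "sertoli_amount": amount,
            "sertoli_fraction": fraction,
            "sertoli_percell": amount / f_sertoli,
            "in_reference": in_reference.to_numpy(),
            "zero_total": total <= 0,
        }
    )
    n_flag = int((~in_reference).sum())
    if n_flag:
        logger.info("%d candidates absent from the human reference (treated as Sertoli-only)", n_flag)
    return out


def call_signatures(
    est: pd.DataFrame,
    ref: CellTypeReference,
    comp: CellComposition,
    cfg: ThresholdConfig,
) -> pd.DataFrame:
    """Apply the three signature criteria to subtraction estimates.

    pass_a: sertoli_fraction >= sertoli_fraction_min            (inclusive)
    pass_b: sertoli_percell  >= ratio_min * Leydig per-cell     (inclusive)
    pass_c: sertoli_percell  >  every germ-type per-cell value  (strict)
    """
    if not ref.is_rescaled():
        ref = ref.rescaled()
    expr = ref.expr.reindex(est["gene_id"]).fillna(0.0)
    germ_types = [c for c in ref.expr.columns if c not in (SERTOLI, LEYDIG)]
    if LEYDIG not in ref.expr.columns:
        raise ValueError("reference lacks a Leydig column")
    percell = est["sertoli_percell"].to_numpy(float)
    leydig = expr[LEYDIG].to_numpy(float)
    germ = expr[germ_types].to_numpy(float)
    pass_a = est["sertoli_fraction"].to_numpy(float) >= cfg.sertoli_fraction_min
    pass_b = percell >= cfg.sertoli_leydig_ratio_min * leydig
    pass_c = (percell[:, None] > germ).all(axis=1)
    max_germ = germ.max(axis=1) if germ_types else np.zeros(len(est))
    out = pd.DataFrame(
        {
            "gene_id": est["gene_id"],
            "sertoli_fraction": est["sertoli_fraction"],
            "sertoli_percell": percell,
            "leydig_percell": leydig,
            "max_germ_percell": max_germ,
            "pass_a": pass_a,
            "pass_b": pass_b,
            "pass_c": pass_c,
            "is_signature": pass_a & pass_b & pass_c,
        }
    )
    logger.info(
        "signature criteria: %d of %d candidates pass all three",
        int(out["is_signature"].sum()), len(out),
    )
    return out


def mouse_overlap(
    signature: Sequence[str], mouse_list: Sequence[str]
) -> tuple[list[str], int, float]:
    """Case-insensitive overlap of the human signature with a mouse
    Sertoli transcript list: (sorted intersection, count, fraction of the
    signature detected in mouse)."""
    sig = canonical_symbols(signature)
    mouse = set(canonical_symbols(mouse_list))
    if not sig or not mouse:
        raise ValueError("both gene lists must be non-empty")
    inter = sorted(set(sig) & mouse)
    return inter, len(inter), len(inter) / len(set(sig))
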