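"""Synthetic cell-type references, compositions and bulk RNA-seq cohorts
with known ground truth.

The generator emulates the study design the pipeline targets: ~1e3-1.7e4
protein-coding genes, 4 complete-spermatogenesis (CS) and 7 Sertoli
cell-only (SCO) bulk libraries of ~17 million reads each, bulk counts
arising as negative-binomial noise around a mixture of per-cell-type
expression profiles, a germ-cell-depleted SCO composition in which somatic
mRNA fractions are enriched roughly 3-fold, and a designated set of
Sertoli-specific "truth" genes whose recovery can be scored exactly.

NB parameterization throughout: variance = mu + phi * mu^2 (phi = 0
degenerates to Poisson).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import CountMatrix
from .signature_screen import (
    RAT5_CELL_TYPES,
    SERTOLI,
    CellComposition,
    CellTypeReference,
)

GERM_TYPES = ("spermatogonia", "pachytene_spermatocytes", "round_spermatids")
HUMAN_PANEL_TYPES = ("Leydig",) + GERM_TYPES  # measured (non-Sertoli) cell types

#: Baseline per-cell expression is log-normal with these log-scale moments.
BASELINE_MEANLOG = 1.0
BASELINE_SDLOG = 1.2
#: Mild per-(gene, cell type) jitter around the shared per-gene baseline.
JITTER_SDLOG = 0.2


def default_composition_cs() -> CellComposition:
    """Relative mRNA-mass composition of a testis with complete
    spermatogenesis: germ cells dominate (~75%)."""
    return CellComposition(
        weights=pd.Series(
            {
                "Sertoli": 0.15,
                "Leydig": 0.10,
                "spermatogonia": 0.10,
                "pachytene_spermatocytes": 0.25,
                "round_spermatids": 0.40,
            }
        )
    )


def default_composition_sco() -> CellComposition:
    """Germ-cell-depleted SCO composition: somatic fractions enriched
    roughly 3-fold over the CS testis (0.25 -> 0.90), residual germ signal
    10% (some SCO biopsies retain hypospermatogenic patches)."""
    germ_total = 0.10
    weights = {"Sertoli": 0.55, "Leydig": 0.35}
    for g in GERM_TYPES:
        weights[g] = germ_total / len(GERM_TYPES)
    return CellComposition(weights=pd.Series(weights))


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic cohort; the recovery-test oracle."""

    signature_genes: list[str]
    decoy_genes: list[str]
    enrichment: dict[str, float]
    composition_cs: dict[str, float]
    composition_sco: dict[str, float]
    library_size: float
    phi: float
    seed: int
    #: signature genes whose SCO Sertoli per-cell expression is aberrant
    aberrant_down: list[str] = field(default_factory=list)
    aberrant_up: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticReferences:
    """Reference bundle produced by :func:`generate_references`.

    ``full_panel`` is the complete human panel *including* the true Sertoli
    column; it is what bulk mixtures are drawn from.  ``human_ref`` is the
    measured panel handed to the pipeline (Sertoli withheld, as in the real
    analysis where no human Sertoli transcriptome was available).
    """

    rat_ref: CellTypeReference
    human_ref: CellTypeReference
    full_panel: pd.DataFrame
    orthologs: pd.DataFrame
    truth: SyntheticTruth


def _rat_symbol(human_symbol: str) -> str:
    return f"RN{human_symbol}"


def generate_references(
    n_genes: int = 1000,
    n_signature: int = 50,
    enrichment: float = 12.0,
    decoy_fraction: float = 0.05,
    decoy_fold: float = 3.5,
    unmapped_fraction: float = 0.05,
    multimap_fraction: float = 0.02,
    seed: int = 17,
) -> SyntheticReferences:
    """Generate rat and human cell-type panels sharing planted truth genes.

    Each gene has a baseline expression level drawn log-normal (meanlog 1,
    sdlog 1.2) shared across cell types, with independent mild
    per-(gene, cell type) jitter per panel.  Signature (truth) genes are
    made Sertoli-specific the way real marker genes are: the non-Sertoli
    columns are *depleted* relative to the Sertoli value by a per-gene
    enrichment factor drawn uniformly from [enrichment, 2*enrichment], with
    one cell type binding exactly, so the realized Sertoli-vs-max-other
    ratio equals the drawn factor and ``enrichment`` is a hard floor.
    Depleting the other columns rather than inflating Sertoli keeps the
    per-column mRNA-mass normalization (every column rescaled to 1e6) from
    eroding the planted ratio.  Near-miss decoys (``decoy_fraction`` of
    genes) get a realized ratio of exactly ``decoy_fold``, narrowly missing
    the 4-fold rat screen and making specificity non-trivial.  A 1:1
    ortholog table links the panels, with configurable fractions of
    unmapped and multi-mapped decoy genes.  ACTB is planted as a high,
    uniformly expressed housekeeping transcript.
    """
    if n_signature >= n_genes:
        raise ValueError("n_signature must be smaller than n_genes")
    if enrichment <= 1:
        raise ValueError("enrichment must exceed 1")
    rng = np.random.default_rng(seed)

    genes = ["ACTB"] + [f"HSG{i:05d}" for i in range(1, n_genes)]
    baseline = rng.lognormal(BASELINE_MEANLOG, BASELINE_SDLOG, size=n_genes)
    baseline[0] = np.quantile(baseline, 0.999) * 2  # ACTB: abundant everywhere

    candidates = rng.permutation(np.arange(1, n_genes))
    truth_idx = np.sort(candidates[:n_signature])
    n_decoys = int(round(decoy_fraction * n_genes))
    decoy_idx = np.sort(candidates[n_signature : n_signature + n_decoys])
    enr = rng.uniform(enrichment, 2.0 * enrichment, size=n_signature)

    def _plant_ratio(df: pd.DataFrame, idx: np.ndarray, ratio: np.ndarray) -> None:
        """Set non-Sertoli columns to sertoli/ratio * u with u <= 1 and one
        binding cell type (u = 1), so the realized Sertoli-vs-max-other
        ratio is exactly ``ratio``."""
        others = [c for c in df.columns if c != SERTOLI]
        sertoli = df.loc[df.index[idx], SERTOLI].to_numpy()
        u = rng.uniform(0.5, 1.0, size=(len(idx), len(others)))
        u[np.arange(len(idx)), rng.integers(0, len(others), size=len(idx))] = 1.0
        df.loc[df.index[idx], others] = (sertoli / ratio)[:, None] * u

    def panel(cell_types: tuple[str, ...]) -> pd.DataFrame:
        jitter = rng.lognormal(0.0, JITTER_SDLOG, size=(n_genes, len(cell_types)))
        jitter[0] = 1.0  # ACTB is uniform across cell types
        expr = baseline[:, None] * jitter
        df = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"),
                          columns=list(cell_types))
        _plant_ratio(df, truth_idx, enr)
        _plant_ratio(df, decoy_idx, np.full(len(decoy_idx), decoy_fold))
        return df

    rat_expr = panel(RAT5_CELL_TYPES)
    rat_expr.index = pd.Index([_rat_symbol(g) for g in genes], name="gene_id")
    human_full = panel((SERTOLI,) + HUMAN_PANEL_TYPES)

    rat_ref = CellTypeReference(panel_id="rat5", expr=rat_expr).rescaled()
    full_scaled = CellTypeReference(panel_id="human_full", expr=human_full).rescaled().expr
    human_ref = CellTypeReference(
        panel_id="human", expr=full_scaled[list(HUMAN_PANEL_TYPES)]
    )

    # ortholog table: truth genes always clean 1:1; some non-truth genes are
    # unmapped or multi-mapped decoys for the mapping report
    non_truth = np.array([i for i in range(n_genes) if i not in set(truth_idx)])
    rng.shuffle(non_truth)
    n_unmapped = int(round(unmapped_fraction * n_genes))
    n_multi = int(round(multimap_fraction * n_genes))
    unmapped = set(non_truth[:n_unmapped].tolist())
    multi = set(non_truth[n_unmapped : n_unmapped + n_multi].tolist())
    rows = []
    for i, g in enumerate(genes):
        if i in unmapped:
            continue
        rows.append((_rat_symbol(g), g))
        if i in multi:
            rows.append((_rat_symbol(g), f"{g}B"))
    orthologs = pd.DataFrame(rows, columns=["rat_gene", "human_gene"])
    dup = orthologs["rat_gene"].duplicated(keep=False)
    orthologs["multi_mapping"] = dup | orthologs["human_gene"].duplicated(keep=False)

    truth = SyntheticTruth(
        signature_genes=[genes[i] for i in truth_idx],
        decoy_genes=[genes[i] for i in decoy_idx],
        enrichment={genes[i]: float(e) for i, e in zip(truth_idx, enr)},
        composition_cs=default_composition_cs().fractions.to_dict(),
        composition_sco=default_composition_sco().fractions.to_dict(),
        library_size=float("nan"),
        phi=float("nan"),
        seed=seed,
    )
    return SyntheticReferences(
        rat_ref=rat_ref,
        human_ref=human_ref,
        full_panel=full_scaled,
        orthologs=orthologs,
        truth=truth,
    )


def expected_mixture(panel: pd.DataFrame, comp: CellComposition) -> pd.Series:
    """Noiseless bulk CPM implied by a panel and a composition (sums to 1e6)."""
    fractions = comp.fractions.reindex(panel.columns)
    if fractions.isna().any():
        missing = fractions.index[fractions.isna()].tolist()
        raise ValueError(f"composition lacks weights for {missing}")
    mix = panel.to_numpy(float) @ fractions.to_numpy()
    mix = mix * (1e6 / mix.sum())
    return pd.Series(mix, index=panel.index, name="expected_cpm")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2); Poisson when phi == 0."""
    if (mu < 0).any():
        raise ValueError("negative NB means")
    if phi < 0:
        raise ValueError("negative dispersion")
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def generate_bulk_cohort(
    refs: SyntheticReferences,
    comp_cs: CellComposition | None = None,
    comp_sco: CellComposition | None = None,
    n_cs: int = 4,
    n_sco: int = 7,
    lib_size: float = 17e6,
    phi: float = 0.1,
    aberrant_down_fraction: float = 0.25,
    aberrant_up_fraction: float = 0.30,
    aberrant_down_fold: float = 0.2,
    aberrant_up_fold: float = 2.5,
    seed: int = 17,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a bulk CS/SCO cohort from the full (Sertoli-inclusive) panel.

    count(g, s) ~ NB(mean = lib_size * mix_group(g) / 1e6, dispersion phi)
    with mix_group the composition-weighted mixture rescaled to 1e6.

    Beyond the composition shift, SCO Sertoli cells themselves express part
    of the signature aberrantly: random subsets of the truth genes have
    their SCO Sertoli per-cell expression multiplied by
    ``aberrant_down_fold`` / ``aberrant_up_fold`` (defaults emulate roughly
    a quarter of the signature strongly reduced and a third elevated).
    These are the differences the median-rescaled signature re-test is
    meant to recover, on top of the global somatic enrichment that the
    rescaling removes.

    Returns (counts, sample table, truth updated with the cohort settings
    and aberrant-gene lists).  The noiseless group mixtures are attached to
    the sample table's ``attrs`` as generator bookkeeping.
    """
    comp_cs = comp_cs or default_composition_cs()
    comp_sco = comp_sco or default_composition_sco()
    if (comp_cs.weights < 0).any() or (comp_sco.weights < 0).any():
        raise ValueError("negative composition weights")
    rng = np.random.default_rng(seed)
    panel = refs.full_panel
    sig = [g for g in refs.truth.signature_genes if g in panel.index]
    n_down = int(round(aberrant_down_fraction * len(sig)))
    n_up = int(round(aberrant_up_fraction * len(sig)))
    chosen = rng.permutation(sig)
    aberrant_down = sorted(chosen[:n_down].tolist())
    aberrant_up = sorted(chosen[n_down : n_down + n_up].tolist())
    panel_sco = panel.copy()
    panel_sco.loc[aberrant_down, SERTOLI] *= aberrant_down_fold
    panel_sco.loc[aberrant_up, SERTOLI] *= aberrant_up_fold
    mix_cs = expected_mixture(panel, comp_cs)
    mix_sco = expected_mixture(panel_sco, comp_sco)

    sample_ids = [f"C{i + 1}" for i in range(n_cs)] + [f"SCO{i + 1}" for i in range(n_sco)]
    groups = ["CS"] * n_cs + ["SCO"] * n_sco
    cols = {}
    for sid, grp in zip(sample_ids, groups):
        mix = mix_cs if grp == "CS" else mix_sco
        mu = lib_size * mix.to_numpy() / 1e6
        cols[sid] = _nb_draw(rng, mu, phi)
    counts = pd.DataFrame(cols, index=panel.index)
    cm = CountMatrix.from_counts(counts)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "histology": [
                "complete spermatogenesis" if g == "CS" else "Sertoli cell-only"
                for g in groups
            ],
            "age": rng.integers(24, 56, size=len(sample_ids)),
            "weight_lbs": rng.integers(136, 305, size=len(sample_ids)),
            "fsh_miu_ml": np.round(
                np.where(
                    np.array(groups) == "CS",
                    rng.uniform(5, 11, size=len(sample_ids)),
                    rng.uniform(8, 32, size=len(sample_ids)),
                ),
                2,
            ),
            "eggs_injected": rng.integers(4, 21, size=len(sample_ids)),
            "embryos": rng.integers(1, 17, size=len(sample_ids)),
        }
    )
    samples.attrs["expected_cpm_cs"] = mix_cs
    samples.attrs["expected_cpm_sco"] = mix_sco

    truth = dataclasses.replace(
        refs.truth,
        composition_cs=comp_cs.fractions.to_dict(),
        composition_sco=comp_sco.fractions.to_dict(),
        library_size=float(lib_size),
        phi=float(phi),
        seed=seed,
        aberrant_down=aberrant_down,
        aberrant_up=aberrant_up,
    )
    return cm, samples, truth


def evaluate_recovery(
    called: "set[str] | list[str]",
    truth: SyntheticTruth,
    universe: "list[str]",
) -> tuple[float, float, pd.DataFrame]:
    """Sensitivity and specificity of a called signature set against truth.

    sensitivity = |called AND truth| / |truth|
    specificity = |non-truth correctly rejected| / |non-truth|
    both over the given gene universe.
    """
    called_set = {g.upper() for g in called}
    truth_set = {g.upper() for g in truth.signature_genes}
    universe_set = {g.upper() for g in universe}
    truth_set &= universe_set
    non_truth = universe_set - truth_set
    tp = len(called_set & truth_set)
    fp = len(called_set & non_truth)
    fn = len(truth_set - called_set)
    tn = len(non_truth) - fp
    sensitivity = tp / len(truth_set) if truth_set else float("nan")
    specificity = tn / len(non_truth) if non_truth else float("nan")
    confusion = pd.DataFrame(
        {"called": [tp, fp], "rejected": [fn, tn]},
        index=pd.Index(["truth", "non_truth"], name=""),
    )
    return sensitivity, specificity, confusion


# ---------------------------------------------------------------------------
# On-disk fixture writing (same formats data_io reads)
# ---------------------------------------------------------------------------


def write_cohort_fixture(
    out_dir: str | Path,
    refs: SyntheticReferences,
    cm: CountMatrix,
    samples: pd.DataFrame,
    truth: SyntheticTruth,
    rng_seed: int = 17,
) -> dict[str, Path]:
    """Write a complete set of pipeline inputs: counts, samples, panels,
    composition, orthologs, an augmentation list and a mouse Sertoli list.

    The mouse list contains 90% of the truth genes plus background symbols,
    emulating the near-complete cross-species detection of genuine Sertoli
    transcripts; the augmentation list holds a few symbols beyond the rat
    screen output to exercise the manual-augmentation path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)
    paths: dict[str, Path] = {}

    paths["counts"] = out_dir / "counts.tsv"
    cm.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    paths["samples"] = out_dir / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["rat_reference"] = out_dir / "rat_reference.tsv"
    refs.rat_ref.expr.to_csv(paths["rat_reference"], sep="\t", index_label="gene_id")
    paths["human_reference"] = out_dir / "human_reference.tsv"
    refs.human_ref.expr.to_csv(paths["human_reference"], sep="\t", index_label="gene_id")
    paths["composition"] = out_dir / "composition_cs.tsv"
    comp = pd.Series(truth.composition_cs).rename_axis("cell_type").rename("weight")
    comp.reset_index().to_csv(paths["composition"], sep="\t", index=False)
    paths["orthologs"] = out_dir / "orthologs.tsv"
    refs.orthologs[["rat_gene", "human_gene"]].to_csv(
        paths["orthologs"], sep="\t", index=False
    )

    non_truth = [g for g in cm.gene_ids if g not in set(truth.signature_genes)]
    augment = list(rng.choice(non_truth, size=min(5, len(non_truth)), replace=False))
    paths["augment"] = out_dir / "augment.txt"
    paths["augment"].write_text("\n".join(augment) + "\n")

    n_keep = int(round(0.9 * len(truth.signature_genes)))
    mouse = list(rng.choice(truth.signature_genes, size=n_keep, replace=False))
    mouse += list(rng.choice(non_truth, size=min(200, len(non_truth)), replace=False))
    paths["mouse"] = out_dir / "mouse_sertoli.txt"
    paths["mouse"].write_text("\n".join(sorted(mouse)) + "\n")

    paths["truth"] = out_dir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
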