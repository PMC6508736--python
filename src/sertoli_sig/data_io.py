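"""Tabular input/output, configuration and logging.

All downstream modules consume the validated containers built here
(:class:`CountMatrix`, sample tables, reference bundles); no scientific
computation happens in this module.  Gene identifiers are plain gene
symbols, matched case-insensitively and stored upper-case, because every
cross-reference in this analysis (rat panel, ortholog map, mouse list) is
symbol-level.

TSV is the canonical on-disk format; CSV is accepted on read only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sertoli_sig")

GROUPS = ("CS", "SCO")

#: Columns expected in a sample (donor) table.
SAMPLE_TABLE_COLUMNS = [
    "sample_id",
    "group",
    "histology",
    "age",
    "weight_lbs",
    "fsh_miu_ml",
    "eggs_injected",
    "embryos",
]

_NUMERIC_SAMPLE_FIELDS = ["age", "weight_lbs", "fsh_miu_ml", "eggs_injected", "embryos"]

#: Strings treated as a missing numeric value in donor tables.
MISSING_TOKENS = {"", "na", "nan", "no data", "nd", "none", "-"}


def configure_logging(verbosity: int = 0) -> None:
    """Send timestamped log lines to stderr. ``verbosity`` 0=warning, 1=info, 2=debug."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ThresholdConfig:
    """All numeric thresholds of the analysis, in one place.

    Defaults are the values used throughout the pipeline: expression filter
    > 0.4 CPM in at least 2 complete-spermatogenesis libraries, FDR < 0.05
    for count-based tests, p <= 0.005 for actin-ratio t-tests, a 4-fold rat
    Sertoli enrichment screen, and the three signature criteria (>= 60%
    Sertoli share, >= 2x Leydig, greater than any germ type).
    """

    cpm_min: float = 0.4
    min_cs_libraries: int = 2
    fdr_max: float = 0.05
    ttest_alpha: float = 0.005
    rat_fold: float = 4.0
    sertoli_fraction_min: float = 0.6
    sertoli_leydig_ratio_min: float = 2.0
    kmeans_k: int = 10
    log_prior: float = 1.0
    seed: int = 17

    def __post_init__(self) -> None:
        for name in (
            "cpm_min",
            "min_cs_libraries",
            "fdr_max",
            "ttest_alpha",
            "rat_fold",
            "sertoli_fraction_min",
            "sertoli_leydig_ratio_min",
            "kmeans_k",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name!r} must be > 0")
        if not (0 < self.sertoli_fraction_min <= 1):
            raise ValueError("sertoli_fraction_min must lie in (0, 1]")
        if self.log_prior < 0:
            raise ValueError("log_prior must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ThresholdConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "thresholds" in payload:
            payload = payload["thresholds"]
        return cls.from_mapping(payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


def canonical_symbols(symbols: Iterable[str]) -> list[str]:
    """Trim whitespace and upper-case gene symbols."""
    return [str(s).strip().upper() for s in symbols]


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with library sizes.

    ``library_sizes`` defaults to column sums but may reflect pre-filter
    totals (e.g. total mapped reads); it must be strictly positive.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    gene_biotype: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts.index = pd.Index(canonical_symbols(self.counts.index), name="gene_id")
        dup_genes = self.counts.index[self.counts.index.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(f"duplicate gene ids: {sorted(dup_genes)}")
        dup_samples = self.counts.columns[self.counts.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValueError(f"duplicate sample ids: {sorted(dup_samples)}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integer count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        ls = self.library_sizes.to_numpy(float)
        if not np.isnan(ls).any() and np.allclose(ls, np.round(ls)):
            self.library_sizes = self.library_sizes.astype(np.int64)
        if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[
                self.library_sizes.isna() | (self.library_sizes <= 0)
            ].tolist()
            raise ValueError(f"library sizes must be > 0 for all samples; bad: {bad}")
        if self.gene_biotype is not None:
            self.gene_biotype = self.gene_biotype.copy()
            self.gene_biotype.index = pd.Index(
                canonical_symbols(self.gene_biotype.index), name="gene_id"
            )
            self.gene_biotype = self.gene_biotype.reindex(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        library_sizes: pd.Series | None = None,
        gene_biotype: pd.Series | None = None,
    ) -> "CountMatrix":
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        return cls(counts=counts.copy(), library_sizes=library_sizes, gene_biotype=gene_biotype)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        genes = canonical_symbols(genes)
        bt = self.gene_biotype.loc[genes] if self.gene_biotype is not None else None
        return CountMatrix(
            counts=self.counts.loc[genes].copy(),
            library_sizes=self.library_sizes.copy(),
            gene_biotype=bt,
        )


def _read_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {format!r}")
    sep = "\t" if format == "tsv" else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a gene x sample count table.

    First column holds gene symbols; an optional ``biotype`` column carries
    per-gene biotype labels; every remaining column is one sample's counts.
    Library sizes are the column sums.
    """
    raw = _read_table(path, format)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need a gene id column plus at least one sample")
    gene_col = raw.columns[0]
    genes = canonical_symbols(raw[gene_col])
    dup = pd.Index(genes)[pd.Index(genes).duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate gene ids: {sorted(dup)}")
    biotype = None
    body = raw.drop(columns=[gene_col])
    if "biotype" in body.columns:
        biotype = pd.Series(body.pop("biotype").values, index=genes, name="biotype")
    try:
        values = body.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count entry ({exc})") from exc
    counts = pd.DataFrame(values.values, index=pd.Index(genes, name="gene_id"),
                          columns=body.columns)
    cm = CountMatrix.from_counts(counts, gene_biotype=biotype)
    logger.info("read %d genes x %d samples from %s", *cm.counts.shape, path)
    return cm


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    if cm.gene_biotype is not None:
        out.insert(0, "biotype", cm.gene_biotype)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read the donor/sample table.

    Returns a DataFrame with ``sample_id`` as a column, ``group`` validated
    against {CS, SCO}, and numeric covariates coerced with missing tokens
    (empty cells, "No data", ...) mapped to NaN.
    """
    df = _read_table(path, format)
    missing_cols = {"sample_id", "group"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: sample table lacks columns {sorted(missing_cols)}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids: {dup}")
    df["group"] = df["group"].astype(str).str.strip().str.upper()
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"{path}: unknown group labels {bad}; expected {GROUPS}")
    for col in _NUMERIC_SAMPLE_FIELDS:
        if col in df.columns:
            cleaned = df[col].map(
                lambda v: np.nan
                if (pd.isna(v) or str(v).strip().lower() in MISSING_TOKENS)
                else v
            )
            df[col] = pd.to_numeric(cleaned)
    return df


def check_samples_match(cm: CountMatrix, samples: pd.DataFrame) -> None:
    """Every count-matrix sample must appear exactly once in the sample table."""
    table_ids = list(samples["sample_id"])
    missing = [s for s in cm.sample_ids if s not in table_ids]
    if missing:
        raise ValueError(f"samples missing from sample table: {missing}")


# ---------------------------------------------------------------------------
# Reference bundle (cell-type panels, composition, orthologs, gene lists)
# ---------------------------------------------------------------------------


def read_reference(path: str | Path, panel_id: str, format: str | None = None):
    """Read a gene x cell-type reference expression table."""
    from .signature_screen import CellTypeReference

    raw = _read_table(path, format)
    if raw.empty:
        raise ValueError(f"{path}: empty reference table")
    gene_col = raw.columns[0]
    genes = canonical_symbols(raw[gene_col])
    body = raw.drop(columns=[gene_col]).astype(float)
    expr = pd.DataFrame(body.values, index=pd.Index(genes, name="gene_id"),
                        columns=body.columns)
    return CellTypeReference(panel_id=panel_id, expr=expr)


def read_composition(path: str | Path, format: str | None = None):
    """Read a relative cell-number table: columns ``cell_type``, ``weight``
    and optionally ``mrna_content``."""
    from .signature_screen import CellComposition

    df = _read_table(path, format)
    if df.empty:
        raise ValueError(f"{path}: empty composition table")
    if not {"cell_type", "weight"} <= set(df.columns):
        raise ValueError(f"{path}: composition needs columns cell_type, weight")
    weights = pd.Series(
        df["weight"].astype(float).values, index=df["cell_type"].astype(str).str.strip()
    )
    mrna = None
    if "mrna_content" in df.columns:
        mrna = pd.Series(df["mrna_content"].astype(float).values, index=weights.index)
    return CellComposition(weights=weights, mrna_content=mrna)


def read_orthologs(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a rat -> human ortholog table (columns ``rat_gene``, ``human_gene``).

    Multi-mapping rows are kept and flagged; the screen later excludes them.
    """
    df = _read_table(path, format)
    if not {"rat_gene", "human_gene"} <= set(df.columns):
        raise ValueError(f"{path}: ortholog table needs columns rat_gene, human_gene")
    df = df.copy()
    df["rat_gene"] = canonical_symbols(df["rat_gene"])
    df["human_gene"] = canonical_symbols(df["human_gene"])
    multi_rat = df["rat_gene"].duplicated(keep=False)
    multi_human = df["human_gene"].duplicated(keep=False)
    df["multi_mapping"] = multi_rat | multi_human
    n_multi = int(df["multi_mapping"].sum())
    if n_multi:
        logger.info("ortholog table: %d multi-mapping rows flagged", n_multi)
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (blank lines and '#' comments skipped)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.upper())
    return out


def read_reference_bundle(paths: Mapping[str, str | Path]) -> dict:
    """Load every reference input declared in a path mapping.

    Recognized keys: ``rat_reference``, ``human_reference``, ``composition``,
    ``orthologs``, ``augment``, ``mouse``.  Absent optional keys yield None
    (``augment`` -> empty list).
    """
    bundle: dict = {}
    if "rat_reference" in paths:
        bundle["rat_reference"] = read_reference(paths["rat_reference"], panel_id="rat5")
    if "human_reference" in paths:
        bundle["human_reference"] = read_reference(paths["human_reference"], panel_id="human")
    if "composition" in paths:
        bundle["composition"] = read_composition(paths["composition"])
    if "orthologs" in paths:
        bundle["orthologs"] = read_orthologs(paths["orthologs"])
    bundle["augment"] = read_gene_list(paths["augment"]) if "augment" in paths else []
    bundle["mouse"] = read_gene_list(paths["mouse"]) if "mouse" in paths else None
    return bundle


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

MANIFEST_NAME = "results_manifest.json"


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: ThresholdConfig | None = None,
    force: bool = False,
) -> dict:
    """Write one TSV per named result table plus a JSON manifest.

    Column order is preserved as given (deterministic); floats use a fixed
    repr so identical runs produce byte-identical files.  An existing
    manifest blocks the write unless ``force`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / MANIFEST_NAME
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True (--force) to overwrite"
        )
    entries = []
    for name, table in tables.items():
        fname = f"{name}.tsv"
        table.to_csv(out_dir / fname, sep="\t", index=False, float_format="%.10g")
        entries.append({"name": name, "file": fname, "rows": int(len(table))})
    manifest = {
        "files": entries,
        "config_hash": config.config_hash() if config is not None else None,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %d tables to %s", len(entries), out_dir)
    return manifest
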