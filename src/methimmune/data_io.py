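"""Matrix and table I/O, validation, and run configuration.

All matrices travel as delimited text (TSV by default, comma accepted) with a
``#``-prefixed provenance header. Methylation is kept on the beta scale
(fraction of methylated signal, in [0, 1]) throughout the pipeline; the
deconvolution model is linear in betas, so no M-value transform is applied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "RunConfig",
    "GeneSet",
    "read_beta_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "collapse_probes_to_genes",
    "read_gene_sets",
    "write_gene_sets",
    "read_sample_sheet",
]

__version__ = "0.1.0"

BETA_TOLERANCE = 1e-9

GROUPS = ("tumor", "normal", "reference")


class ValidationError(ValueError):
    """Raised when an input matrix or table violates its contract."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Gene x sample matrix of methylation beta values.

    Parameters
    ----------
    values
        DataFrame with genes as the index and samples as columns. All finite
        entries must lie in [0, 1] (tolerance ``BETA_TOLERANCE``); missing
        values stay as NaN and are counted, never imputed.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(v)
        v = v.astype(float)
        if not v.index.is_unique:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene_ids: {dups[:5]}")
        if not v.columns.is_unique:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_ids: {dups[:5]}")
        arr = v.to_numpy()
        finite = np.isfinite(arr)
        bad = finite & ((arr < -BETA_TOLERANCE) | (arr > 1.0 + BETA_TOLERANCE))
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                f"({v.index[r]}, {v.columns[c]})={arr[r, c]:g}"
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValidationError(
                f"{bad.sum()} beta value(s) outside [0, 1]: {', '.join(cells)}"
            )
        self.values = v

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_genes(self, genes: Sequence) -> "BetaMatrix":
        """Subset to ``genes`` (in that order); missing genes raise."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        return BetaMatrix(self.values.loc[list(genes)])


SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "group",
    "cancer_type",
    "cell_type",
    "survival_time",
    "event",
    "stage",
    "tumor_size",
)


@dataclass
class SampleSheet:
    """Per-sample metadata: tumor/normal group, cancer type, optional
    cell-type label (reference panels) and clinical fields."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "sample_id" not in t.columns or "group" not in t.columns:
            raise ValidationError("sample sheet needs sample_id and group columns")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_ids in sheet: {dups[:5]}")
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        for col in SAMPLE_SHEET_COLUMNS:
            if col not in t.columns:
                t[col] = np.nan
        self.table = t.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def subset(self, sample_ids: Sequence) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].reset_index(drop=True))

    def samples_where(self, **conditions) -> list:
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])


@dataclass
class RunConfig:
    """Run-wide analysis parameters.

    Defaults follow the study conditions of the underlying method: immune
    infiltration fractions below 0.01 are reported as zero, consensus
    clustering scans k = 2..20 with 100 resamples at subsample fraction 0.8,
    and calls are made at alpha = 0.05 with Benjamini-Hochberg correction.
    """

    entropy_threshold_mode: str = "top_m"   # top_m | quantile | absolute
    entropy_threshold_value: float = 350
    entropy_pseudocount: float = 1e-6
    high_entropy_specific: bool = False
    infiltration_threshold: float = 0.01
    k_min: int = 2
    k_max: int = 20
    n_resamples: int = 100
    subsample_fraction: float = 0.8
    select_k_tolerance: float = 0.1
    alpha: float = 0.05
    correction: str = "fdr_bh"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.infiltration_threshold < 1 and self.infiltration_threshold != 0:
            raise ValidationError("infiltration_threshold must be in [0, 1)")
        if not 0 < self.subsample_fraction <= 1:
            raise ValidationError("subsample_fraction must be in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValidationError("need 2 <= k_min <= k_max")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.entropy_threshold_mode not in ("top_m", "quantile", "absolute"):
            raise ValidationError(f"unknown threshold mode {self.entropy_threshold_mode!r}")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _provenance_header(config: RunConfig | None = None) -> str:
    seed = "NA" if config is None else config.seed
    chash = "NA" if config is None else config.config_hash()
    return f"# methimmune v{__version__} seed={seed} config={chash}"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path, orientation: str = "genes") -> BetaMatrix:
    """Read a delimited beta matrix.

    Parameters
    ----------
    orientation
        ``"genes"`` if rows are genes (the native layout), ``"samples"`` if
        rows are samples (transposed on read).
    """
    if orientation not in ("genes", "samples"):
        raise ValueError("orientation must be 'genes' or 'samples'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except Exception as exc:  # pandas errors carry line info in the message
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    nonnum = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if nonnum:
        for c in nonnum:
            coerced = pd.to_numeric(df[c], errors="coerce")
            newly_bad = coerced.isna() & df[c].notna()
            if newly_bad.any():
                row = df.index[newly_bad.argmax()]
                raise ParseError(
                    f"non-numeric value in {path} at row {row!r}, column {c!r}"
                )
            df[c] = coerced
    if orientation == "samples":
        df = df.T
    return BetaMatrix(df)


def write_matrix(df: pd.DataFrame | BetaMatrix, path, config: RunConfig | None = None,
                 index_label: str = "gene_id") -> None:
    """Write a matrix as delimited text with a provenance header line."""
    if isinstance(df, BetaMatrix):
        df = df.values
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config) + "\n")
        df.to_csv(fh, sep=sep, index_label=index_label, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep=_sep_for(path), comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config) + "\n")
        df.to_csv(fh, sep=_sep_for(path), index=False, float_format="%.17g")


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(read_table(path))


def collapse_probes_to_genes(probe_matrix: pd.DataFrame,
                             probe_to_gene: Mapping) -> BetaMatrix:
    """Average probe-level betas onto gene level.

    Each gene's beta per sample is the arithmetic mean of its mapped probes'
    betas over non-missing probes; probes mapping to no gene are dropped, and
    a gene whose probes are all missing in a sample stays missing there.
    """
    if isinstance(probe_matrix, BetaMatrix):
        probe_matrix = probe_matrix.values
    if not probe_to_gene:
        raise ValidationError("probe_to_gene mapping is empty")
    mapped = [p for p in probe_matrix.index if p in probe_to_gene]
    if not mapped:
        raise ValidationError("no probe in the matrix maps to a gene")
    sub = probe_matrix.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene_id")
    collapsed = sub.groupby(genes, sort=False).mean()
    return BetaMatrix(collapsed)


def read_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file: name, description, then member genes, tab-separated.

    Duplicate members within a set are dropped (first occurrence kept).
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name, desc, tuple(dict.fromkeys(genes))))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
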