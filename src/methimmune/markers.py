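"""Cell-type-specific marker selection by Shannon entropy.

A gene that is methylated uniformly across the purified immune-cell
populations carries no cell-type information; a gene whose methylation is
concentrated in (or depleted from) one population is a candidate marker. The
score is the Shannon entropy of the gene's relative methylation profile across
the N cell-type means,

    H0 = -sum_s p_s log2 p_s,   p_s = (beta_s + eps) / sum_t (beta_t + eps),

which is maximal (log2 N) for a flat profile and drops as the profile
concentrates. Specificity is therefore log2 N - H0; markers are the most
specific genes. (A configuration switch inverts the direction for users who
want the opposite convention.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import BetaMatrix, GeneSet, RunConfig, SampleSheet, ValidationError

__all__ = [
    "EntropyScore",
    "SignatureMatrix",
    "compute_entropy",
    "entropy_profile",
    "select_markers",
    "hypergeometric_enrichment",
    "enrichment_of_markers",
]


@dataclass
class EntropyScore:
    gene_id: str
    H0: float                      # bits
    p_profile: np.ndarray          # relative methylation, sums to 1
    assigned_cell_type: str        # cell type of maximal deviation
    direction: str                 # hyper | hypo in the assigned type
    specificity: float             # log2 N - H0

    def __post_init__(self) -> None:
        n = len(self.p_profile)
        if not -1e-9 <= self.H0 <= np.log2(n) + 1e-9:
            raise ValidationError(f"entropy {self.H0} outside [0, log2 {n}]")
        if abs(self.p_profile.sum() - 1.0) > 1e-9:
            raise ValidationError("p_profile must sum to 1")


@dataclass
class SignatureMatrix:
    """Marker-gene x cell-type matrix of mean betas, with per-gene entropy,
    assigned cell type and direction. This is the design matrix of the
    deconvolution model."""

    means: pd.DataFrame
    entropy: pd.Series
    assigned_cell_type: pd.Series
    direction: pd.Series

    def __post_init__(self) -> None:
        arr = self.means.to_numpy()
        if np.isnan(arr).any() or ((arr < -1e-9) | (arr > 1 + 1e-9)).any():
            raise ValidationError("signature betas must be finite and in [0, 1]")
        for s in (self.entropy, self.assigned_cell_type, self.direction):
            if not s.index.equals(self.means.index):
                raise ValidationError("signature metadata must share the gene index")
        if not self.assigned_cell_type.isin(self.means.columns).all():
            raise ValidationError("assigned cell types must be signature columns")

    @property
    def genes(self) -> list:
        return list(self.means.index)

    @property
    def cell_types(self) -> list:
        return list(self.means.columns)

    @property
    def marker_counts(self) -> pd.Series:
        return (self.assigned_cell_type.value_counts()
                .reindex(self.means.columns, fill_value=0))

    def to_frame(self) -> pd.DataFrame:
        out = self.means.copy()
        out["entropy"] = self.entropy
        out["assigned_cell_type"] = self.assigned_cell_type
        out["direction"] = self.direction
        return out.rename_axis("gene_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        meta = ["entropy", "assigned_cell_type", "direction"]
        means = df.drop(columns=meta)
        return cls(means, df["entropy"], df["assigned_cell_type"], df["direction"])


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def _entropy_bits(p: np.ndarray) -> np.ndarray:
    logp = np.log2(p, out=np.zeros_like(p), where=p > 0)
    return -(p * logp).sum(axis=-1)


def entropy_profile(means: np.ndarray, pseudocount: float = 1e-6
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized relative-methylation profiles and entropies.

    ``means`` is gene x cell-type; returns (p, H0) with p summing to 1 per row.
    """
    means = np.asarray(means, dtype=float)
    shifted = means + pseudocount
    totals = shifted.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise ValidationError("all-zero methylation profile with zero pseudocount")
    p = shifted / totals
    return p, _entropy_bits(p)


def compute_entropy(gene_betas: Sequence[float], pseudocount: float = 1e-6,
                    cell_types: Sequence[str] | None = None,
                    gene_id: str = "") -> EntropyScore:
    """Entropy score of one gene's per-cell-type mean beta vector."""
    b = np.asarray(gene_betas, dtype=float)
    if b.ndim != 1 or len(b) < 2:
        raise ValidationError("need a vector of >= 2 cell-type means")
    if np.isnan(b).any() or (b < 0).any() or (b > 1).any():
        raise ValidationError("betas must be finite and in [0, 1]")
    p, h = entropy_profile(b[None, :], pseudocount)
    n = len(b)
    if cell_types is None:
        cell_types = [f"CT{i + 1}" for i in range(n)]
    dev = b - (b.sum() - b) / (n - 1)          # beta_s minus mean of the others
    j = int(np.argmax(np.abs(dev)))
    return EntropyScore(
        gene_id=gene_id, H0=float(h[0]), p_profile=p[0],
        assigned_cell_type=cell_types[j],
        direction="hyper" if dev[j] >= 0 else "hypo",
        specificity=float(np.log2(n) - h[0]),
    )


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def cell_type_means(reference: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-cell-type mean betas over replicates; genes with any missing value
    across the panel are dropped (entropy and deconvolution need complete
    vectors)."""
    ref_rows = sheet.table[sheet.table["sample_id"].isin(reference.sample_ids)]
    if ref_rows["cell_type"].isna().any():
        bad = ref_rows.loc[ref_rows["cell_type"].isna(), "sample_id"].tolist()
        raise ValidationError(f"reference samples without cell_type label: {bad[:5]}")
    groups = ref_rows.groupby("cell_type")["sample_id"].apply(list)
    if (groups.str.len() < 1).any():
        raise ValidationError("every cell type needs >= 1 replicate")
    complete = reference.values.dropna(axis=0)
    means = pd.DataFrame(
        {ct: complete[samples].mean(axis=1) for ct, samples in groups.items()})
    return means[sorted(means.columns, key=list(groups.index).index)]


def select_markers(reference: BetaMatrix, sheet: SampleSheet,
                   config: RunConfig | None = None) -> SignatureMatrix:
    """Score every complete gene and retain the most cell-type-specific ones.

    Threshold modes (``config.entropy_threshold_mode``):
      - ``top_m``: keep the M most specific genes (default);
      - ``quantile``: keep genes with specificity above the given quantile;
      - ``absolute``: keep genes with specificity >= the given cutoff in bits.
    """
    config = config or RunConfig()
    means = cell_type_means(reference, sheet)
    n_types = means.shape[1]
    p, h = entropy_profile(means.to_numpy(), config.entropy_pseudocount)
    spec = np.log2(n_types) - h
    if config.high_entropy_specific:
        spec = h

    mode, value = config.entropy_threshold_mode, config.entropy_threshold_value
    order = np.argsort(-spec, kind="stable")
    if mode == "top_m":
        keep = order[: int(value)]
    elif mode == "quantile":
        cutoff = np.quantile(spec, value)
        keep = order[spec[order] > cutoff]
    else:  # absolute
        keep = order[spec[order] >= value]
    if len(keep) == 0:
        raise ValidationError(
            "no genes pass the specificity threshold; lower the cutoff or use top_m")

    M = means.to_numpy()
    others_mean = (M.sum(axis=1, keepdims=True) - M) / (n_types - 1)
    dev = M - others_mean
    j = np.abs(dev).argmax(axis=1)
    rows = np.arange(len(means))
    assigned = np.asarray(means.columns)[j]
    direction = np.where(dev[rows, j] >= 0, "hyper", "hypo")

    idx = means.index[keep]
    return SignatureMatrix(
        means=means.iloc[keep],
        entropy=pd.Series(h[keep], index=idx, name="entropy"),
        assigned_cell_type=pd.Series(assigned[keep], index=idx, name="assigned_cell_type"),
        direction=pd.Series(direction[keep], index=idx, name="direction"),
    )


# ---------------------------------------------------------------------------
# enrichment (shared with the transcriptome module)
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(query: Iterable, gene_sets: Sequence[GeneSet],
                              universe: Iterable, alpha: float = 0.05,
                              correction: str = "fdr_bh") -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set.

    p is the hypergeometric upper tail P(X >= overlap) with population =
    universe, successes = set members in the universe, draws = |query|;
    adjusted across sets (Benjamini-Hochberg by default).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    query = set(query) & universe
    rows = []
    for gs in gene_sets:
        members = set(gs.genes) & universe
        overlap = len(query & members)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append({
            "set_name": gs.name, "set_size": len(members), "query_size": len(query),
            "universe_size": len(universe), "overlap": overlap, "p_value": min(p, 1.0),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method=correction)[1]
        table["significant"] = table["q_value"] < alpha
        table = table.sort_values(["p_value", "set_name"], kind="stable",
                                  ignore_index=True)
    return table


def enrichment_of_markers(signature: SignatureMatrix | Iterable,
                          gene_sets: Sequence[GeneSet], universe: Iterable,
                          alpha: float = 0.05) -> pd.DataFrame:
    genes = signature.genes if isinstance(signature, SignatureMatrix) else signature
    if not set(genes) <= set(universe):
        raise ValidationError("marker genes must be contained in the universe")
    return hypergeometric_enrichment(genes, gene_sets, universe, alpha=alpha)
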