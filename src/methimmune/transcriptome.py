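"""Transcriptome integration for immune subtypes.

Covers: (i) per-subtype correlation between marker-gene methylation and gene
expression against a sample-permutation baseline; (ii) differential expression
between "increased" subtypes and normals (Welch t, BH, fold-change filter);
(iii) immune-checkpoint gene testing across subtypes (Kruskal-Wallis with the
star-tier convention); (iv) enrichment of DE sets (shared hypergeometric
test); and (v) import of externally computed per-sample scores (e.g.
ESTIMATE or TIDE, which are third-party algorithms run outside this package)
followed by the same cross-subtype comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import BetaMatrix, ValidationError, read_table
from .markers import hypergeometric_enrichment

__all__ = [
    "CorrelationReport",
    "DEResult",
    "significance_tier",
    "correlate_meth_expr",
    "differential_expression",
    "de_by_increased_cell_type",
    "checkpoint_differential",
    "enrich_de_sets",
    "import_external_scores",
]

_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_tier(q: float) -> str:
    """Star annotation: **** q<=1e-4, *** q<=1e-3, ** q<=0.01, * q<=0.05, ns."""
    if np.isnan(q):
        return "ns"
    for cut, sym in _TIERS:
        if q <= cut:
            return sym
    return "ns"


# ---------------------------------------------------------------------------
# methylation-expression correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    per_gene: pd.DataFrame        # (subtype, gene, r, n)
    per_subtype: pd.DataFrame     # observed mean |r|, baseline mean/sd, rank p
    n_permutations: int
    seed: int | None
    n_excluded_zero_variance: int = 0


def correlate_meth_expr(meth: BetaMatrix, expr: pd.DataFrame, labels: pd.Series,
                        n_permutations: int = 1000, seed: int | None = None
                        ) -> CorrelationReport:
    """Observed per-gene Pearson r between beta and expression within each
    subtype, against a baseline where the expression samples are permuted
    (breaking the sample pairing but keeping both marginals).

    The per-subtype rank-based p is (1 + #{baseline mean|r| >= observed}) /
    (n_permutations + 1).
    """
    labels = pd.Series(labels)
    genes = [g for g in meth.values.index if g in expr.index]
    if not genes:
        raise ValidationError("no shared genes between methylation and expression")
    rng = np.random.default_rng(seed)
    per_gene_rows, per_sub_rows = [], []
    excluded = 0
    for subtype in sorted(labels.unique(), key=str):
        ids = [s for s in labels.index[labels == subtype]
               if s in meth.values.columns and s in expr.columns]
        n = len(ids)
        if n < 3:
            continue
        B = meth.values.loc[genes, ids].to_numpy()
        E = expr.loc[genes, ids].to_numpy()
        r_obs, keep = _rowwise_pearson(B, E)
        excluded += int((~keep).sum())
        for g, r, k in zip(genes, r_obs, keep):
            if k:
                per_gene_rows.append({"subtype": subtype, "gene_id": g,
                                      "r": float(r), "n": n})
        obs_stat = float(np.abs(r_obs[keep]).mean())
        base = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(n)
            r_b, keep_b = _rowwise_pearson(B, E[:, perm])
            base[b] = np.abs(r_b[keep_b]).mean() if keep_b.any() else 0.0
        p = (1 + np.sum(base >= obs_stat)) / (n_permutations + 1)
        per_sub_rows.append({
            "subtype": subtype, "n_samples": n, "n_genes": int(keep.sum()),
            "observed_mean_abs_r": obs_stat,
            "baseline_mean_abs_r": float(base.mean()),
            "baseline_sd": float(base.std()),
            "p_value": float(p),
        })
    return CorrelationReport(
        per_gene=pd.DataFrame(per_gene_rows),
        per_subtype=pd.DataFrame(per_sub_rows),
        n_permutations=n_permutations, seed=seed,
        n_excluded_zero_variance=excluded)


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A ** 2).sum(axis=1))
    sb = np.sqrt((B ** 2).sum(axis=1))
    keep = (sa > 0) & (sb > 0)
    r = np.zeros(len(A))
    r[keep] = (A[keep] * B[keep]).sum(axis=1) / (sa[keep] * sb[keep])
    return np.clip(r, -1.0, 1.0), keep


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    table: pd.DataFrame                    # gene, log2fc, t, p, q, de
    de_genes: tuple
    n_excluded_constant: int
    alpha: float
    min_abs_log2fc: float
    per_cell_type: dict = field(default_factory=dict)   # cell type -> gene tuple

    @property
    def union_genes(self) -> tuple:
        if self.per_cell_type:
            u: set = set()
            for genes in self.per_cell_type.values():
                u |= set(genes)
            return tuple(sorted(u))
        return self.de_genes


def differential_expression(expr: pd.DataFrame, group_a, group_b,
                            alpha: float = 0.05, min_abs_log2fc: float = 1.0,
                            log_transformed: bool = True) -> DEResult:
    """Welch t per gene between sample sets A and B on log2 expression.

    DE iff BH q < alpha and |log2 fold change| >= ``min_abs_log2fc``
    (the "strictly selected" convention). Raw-scale input is log2(x + 1)
    transformed first; constant genes are excluded and counted.
    """
    a = [s for s in group_a if s in expr.columns]
    b = [s for s in group_b if s in expr.columns]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 samples per side")
    E = expr[a + b].astype(float)
    if not log_transformed:
        E = np.log2(E + 1)
    A, B = E[a].to_numpy(), E[b].to_numpy()
    keep = ~((A.std(axis=1) == 0) & (B.std(axis=1) == 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A[keep], B[keep], axis=1, equal_var=False)
    lfc = A[keep].mean(axis=1) - B[keep].mean(axis=1)
    table = pd.DataFrame({
        "gene_id": E.index[keep],
        "log2fc": lfc,
        "t": t,
        "p_value": p,
    })
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["de"] = (table["q_value"] < alpha) & (table["log2fc"].abs() >= min_abs_log2fc)
    de_genes = tuple(table.loc[table["de"], "gene_id"])
    return DEResult(table=table, de_genes=de_genes,
                    n_excluded_constant=int((~keep).sum()),
                    alpha=alpha, min_abs_log2fc=min_abs_log2fc)


def de_by_increased_cell_type(expr: pd.DataFrame, annotation, labels: pd.Series,
                              sheet, alpha: float = 0.05,
                              min_abs_log2fc: float = 1.0,
                              log_transformed: bool = True) -> DEResult:
    """Per cell type, pool the samples of subtypes annotated "increase" for
    that cell type and test them against the same cancers' normals; the
    per-cell-type DE sets and their union are recorded."""
    ann = annotation.table if hasattr(annotation, "table") else annotation
    labels = pd.Series(labels)
    meta = sheet.table
    per_ct: dict = {}
    tables = []
    for ct in sorted(ann["cell_type"].unique()):
        inc = ann[(ann["cell_type"] == ct) & (ann["call"] == "increase")]
        if inc.empty:
            per_ct[ct] = tuple()
            continue
        tumor_ids = [s for s in labels.index
                     if labels[s] in set(inc["subtype"]) and s in expr.columns]
        cancers = set(inc["cancer_type"])
        normal_ids = [s for s in meta.loc[(meta["group"] == "normal")
                                          & meta["cancer_type"].isin(cancers),
                                          "sample_id"] if s in expr.columns]
        if len(tumor_ids) < 2 or len(normal_ids) < 2:
            per_ct[ct] = tuple()
            continue
        res = differential_expression(expr, tumor_ids, normal_ids, alpha=alpha,
                                      min_abs_log2fc=min_abs_log2fc,
                                      log_transformed=log_transformed)
        per_ct[ct] = res.de_genes
        tables.append(res.table.assign(cell_type=ct))
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    union = tuple(sorted({g for genes in per_ct.values() for g in genes}))
    return DEResult(table=table, de_genes=union, n_excluded_constant=0,
                    alpha=alpha, min_abs_log2fc=min_abs_log2fc,
                    per_cell_type=per_ct)


# ---------------------------------------------------------------------------
# checkpoint genes and imported scores
# ---------------------------------------------------------------------------

def checkpoint_differential(expr: pd.DataFrame, labels: pd.Series,
                            checkpoint_genes) -> pd.DataFrame:
    """Kruskal-Wallis per checkpoint gene across subtypes, BH across the
    tested genes, star tiers on q. Genes absent from the matrix are reported
    with flag "missing" and not tested."""
    labels = pd.Series(labels)
    ids = [s for s in labels.index if s in expr.columns]
    if pd.Series(labels[ids]).nunique() < 2:
        raise ValidationError("checkpoint testing needs >= 2 subtypes")
    groups = {lab: [s for s in ids if labels[s] == lab]
              for lab in sorted(labels[ids].unique(), key=str)}
    rows = []
    for gene in checkpoint_genes:
        if gene not in expr.index:
            rows.append({"gene_id": gene, "statistic": np.nan, "p_value": np.nan,
                         "flag": "missing"})
            continue
        vals = [expr.loc[gene, s_ids].to_numpy(dtype=float)
                for s_ids in groups.values()]
        if np.ptp(np.concatenate(vals)) == 0:
            rows.append({"gene_id": gene, "statistic": 0.0, "p_value": 1.0, "flag": ""})
            continue
        h, p = stats.kruskal(*vals)
        rows.append({"gene_id": gene, "statistic": float(h), "p_value": float(p),
                     "flag": ""})
    table = pd.DataFrame(rows)
    tested = table["p_value"].notna()
    table["q_value"] = np.nan
    if tested.any():
        table.loc[tested, "q_value"] = multipletests(table.loc[tested, "p_value"],
                                                     method="fdr_bh")[1]
    table["tier"] = table["q_value"].apply(
        lambda q: significance_tier(q) if pd.notna(q) else "ns")
    return table


def enrich_de_sets(de: DEResult, gene_sets, universe,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of the DE union set (shared implementation
    with the marker module)."""
    return hypergeometric_enrichment(de.union_genes, gene_sets, universe,
                                     alpha=alpha)


def import_external_scores(scores, labels: pd.Series,
                           score_column: str = "score") -> dict:
    """Compare externally computed per-sample scores (e.g. ESTIMATE/TIDE)
    across subtypes: Kruskal-Wallis overall plus pairwise Mann-Whitney with
    BH, star tiers. Unmatched samples are dropped and counted."""
    if not isinstance(scores, pd.DataFrame):
        scores = read_table(scores)
    if "sample_id" not in scores.columns or score_column not in scores.columns:
        raise ValidationError(f"score table needs sample_id and {score_column!r}")
    labels = pd.Series(labels)
    merged = scores.set_index("sample_id")[score_column]
    shared = [s for s in labels.index if s in merged.index]
    dropped = (len(labels) - len(shared)) + int((~merged.index.isin(labels.index)).sum())
    sub = pd.DataFrame({"subtype": labels[shared], "score": merged[shared]})
    groups = {lab: g["score"].to_numpy() for lab, g in sub.groupby("subtype")}
    if len(groups) < 2:
        raise ValidationError("score comparison needs >= 2 subtypes")
    if np.var(np.concatenate(list(groups.values()))) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups.values())
    pairs = []
    labs = sorted(groups, key=str)
    for i, la in enumerate(labs):
        for lb in labs[i + 1:]:
            if np.var(np.concatenate([groups[la], groups[lb]])) == 0:
                u, pp = 0.0, 1.0
            else:
                u, pp = stats.mannwhitneyu(groups[la], groups[lb],
                                           alternative="two-sided")
            pairs.append({"subtype_a": la, "subtype_b": lb,
                          "statistic": float(u), "p_value": float(pp)})
    pairwise = pd.DataFrame(pairs)
    if len(pairwise):
        pairwise["q_value"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
        pairwise["tier"] = pairwise["q_value"].apply(significance_tier)
    return {"statistic": float(h), "p_value": float(p),
            "tier": significance_tier(float(p)),
            "pairwise": pairwise, "n_dropped": int(dropped),
            "per_subtype": sub.groupby("subtype")["score"].describe()}
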