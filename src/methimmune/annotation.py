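"""Subtype annotation against normal tissue.

Every (cancer, subtype, cell type) is called increase / decrease / nochange by
comparing the subtype's reported infiltration fractions with the same cancer's
normal samples: Welch's two-sample t-test (a Mann-Whitney switch is provided),
Benjamini-Hochberg adjusted within each cancer across its subtype x cell-type
tests. A call is non-nochange iff q < alpha, with the direction given by the
sign of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import SampleSheet, ValidationError

__all__ = ["AnnotationTable", "annotate_subtypes", "summarize_annotations"]

_SIGN = {"increase": "+", "decrease": "-", "nochange": "="}


@dataclass
class AnnotationTable:
    """Rows keyed by (cancer, subtype, cell type) with the test statistics and
    the three-way call; every subtype carries exactly one row per cell type."""

    table: pd.DataFrame
    alpha: float
    cell_types: list

    def __post_init__(self) -> None:
        t = self.table
        per_subtype = t.groupby(["cancer_type", "subtype"]).size()
        if (per_subtype != len(self.cell_types)).any():
            raise ValidationError("each subtype needs one row per cell type")
        tested = t["q_value"].notna()
        bad = tested & (((t["q_value"] >= self.alpha) & (t["call"] != "nochange"))
                        | ((t["q_value"] < self.alpha) & (t["call"] == "nochange")))
        if bad.any():
            raise ValidationError("calls inconsistent with q-values")


def _test(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if np.var(x) == 0 and np.var(y) == 0:
        return (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
    if method == "mannwhitney":
        s, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        s, p = stats.ttest_ind(x, y, equal_var=False)
    return float(s), float(p)


def annotate_subtypes(fractions, labels: pd.Series, sheet: SampleSheet,
                      alpha: float = 0.05, correction: str = "fdr_bh",
                      method: str = "welch", adjust_scope: str = "cancer"
                      ) -> AnnotationTable:
    """Call each (cancer, subtype, cell type) against that cancer's normals.

    ``labels`` maps tumor sample -> subtype label (any hashable; labels of the
    form "CANCER:k" work directly with subtype_cohort output). Cancers with no
    testable normals get all-nochange calls flagged "untestable".
    ``adjust_scope`` is "cancer" (BH within each cancer) or "global".
    """
    frac = fractions.fractions if hasattr(fractions, "fractions") else fractions
    labels = pd.Series(labels)
    meta = sheet.table
    cell_types = list(frac.columns)
    rows = []
    tumor_meta = meta.loc[[s for s in labels.index if s in meta.index]]
    for cancer, sub_meta in tumor_meta.groupby("cancer_type", sort=True):
        normal_ids = [s for s in meta.loc[(meta["group"] == "normal")
                                          & (meta["cancer_type"] == cancer),
                                          "sample_id"] if s in frac.index]
        normals = frac.loc[normal_ids]
        untestable = len(normals) < 2
        for subtype in sorted(labels.loc[sub_meta["sample_id"]].unique(), key=str):
            ids = [s for s in sub_meta["sample_id"] if labels[s] == subtype]
            grp = frac.loc[ids]
            for ct in cell_types:
                row = {"cancer_type": cancer, "subtype": subtype, "cell_type": ct,
                       "n_subtype": len(grp), "n_normal": len(normals),
                       "mean_subtype": grp[ct].mean(),
                       "mean_normal": normals[ct].mean() if len(normals) else np.nan}
                if untestable or len(grp) < 2:
                    row.update(statistic=np.nan, p_value=np.nan,
                               flag="untestable" if untestable else "skipped")
                else:
                    s, p = _test(grp[ct].to_numpy(), normals[ct].to_numpy(), method)
                    row.update(statistic=s, p_value=p, flag="")
                rows.append(row)
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    tested = table["p_value"].notna()
    if tested.any():
        if adjust_scope == "global":
            table.loc[tested, "q_value"] = multipletests(
                table.loc[tested, "p_value"], method=correction)[1]
        else:
            for _, idx in table[tested].groupby("cancer_type").groups.items():
                table.loc[idx, "q_value"] = multipletests(
                    table.loc[idx, "p_value"], method=correction)[1]
    table["call"] = "nochange"
    sig = tested & (table["q_value"] < alpha)
    table.loc[sig, "call"] = np.where(
        table.loc[sig, "mean_subtype"] > table.loc[sig, "mean_normal"],
        "increase", "decrease")
    return AnnotationTable(table=table, alpha=alpha, cell_types=cell_types)


def summarize_annotations(annotation: AnnotationTable
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell-type counts of subtypes called increase/decrease/nochange, and
    one pattern string per subtype (e.g. ``"CD4-,CD8+,CD56="``)."""
    t = annotation.table
    counts = (t.pivot_table(index="cell_type", columns="call", aggfunc="size",
                            fill_value=0)
              .reindex(annotation.cell_types)
              .reindex(columns=["increase", "decrease", "nochange"], fill_value=0))
    counts.columns.name = None
    n_subtypes = t.groupby(["cancer_type", "subtype"]).ngroups
    if not (counts.sum(axis=1) == n_subtypes).all():
        raise ValidationError("annotation counts must conserve the subtype total")
    patterns = (t.assign(token=lambda d: d["cell_type"] + d["call"].map(_SIGN))
                .groupby(["cancer_type", "subtype"])["token"]
                .apply(",".join).rename("pattern").reset_index())
    return counts.reset_index(), patterns
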