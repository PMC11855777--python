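"""Phenotype integration: survival, clinical stage, and tumor size by subtype.

Overall survival is summarized per subtype with the Kaplan-Meier product-limit
estimator and compared across subtypes with the standard log-rank chi-square
test (g - 1 degrees of freedom, hypergeometric variance, ties handled at the
pooled event times). Stage associations use a chi-square test of independence
on the subtype x stage contingency table, with a linear-by-linear trend option
for ordinal stage and an exact fallback for sparse 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .data_io import ValidationError

__all__ = [
    "SurvivalCurve",
    "kaplan_meier",
    "logrank_test",
    "stage_association",
    "size_association",
]


@dataclass
class SurvivalCurve:
    """Per-group KM curves plus the cross-group log-rank test."""

    curves: dict                      # group -> DataFrame(time, survival, at_risk)
    statistic: float
    p_value: float
    degrees_freedom: int
    all_censored_groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for g, df in self.curves.items():
            s = df["survival"].to_numpy()
            if len(s) and (np.diff(s) > 1e-12).any():
                raise ValidationError(f"KM curve for {g!r} must be non-increasing")
            if len(s) and s[0] > 1 + 1e-12:
                raise ValidationError("KM curves start at <= 1")
        if self.statistic < 0:
            raise ValidationError("log-rank statistic must be >= 0")


def _clean(times, events, groups) -> pd.DataFrame:
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       "group": np.asarray(groups)})
    if (df["time"] < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event flags must be 0/1")
    return df


def kaplan_meier(times, events, group_labels) -> SurvivalCurve:
    """Product-limit survival estimate per group; tied event times enter the
    product simultaneously. Groups with no events get a flat curve at 1 and
    are flagged."""
    df = _clean(times, events, group_labels)
    if df["event"].sum() < 1:
        raise ValidationError("need at least one observed event overall")
    curves, flat = {}, []
    for g, sub in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tab = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        curves[g] = pd.DataFrame({
            "time": tab.index.to_numpy(dtype=float),
            "survival": surv.reindex(tab.index).to_numpy(),
            "at_risk": tab["at_risk"].to_numpy(dtype=int),
        })
        if sub["event"].sum() == 0:
            flat.append(g)
    if df["group"].nunique() >= 2:
        stat, p, dof = logrank_test(df["time"], df["event"], df["group"])
    else:
        stat, p, dof = 0.0, 1.0, 0
    return SurvivalCurve(curves=curves, statistic=stat, p_value=p,
                         degrees_freedom=dof, all_censored_groups=flat)


def logrank_test(times, events, group_labels) -> tuple[float, float, int]:
    """Standard log-rank chi-square over the pooled event times; returns
    (statistic, p, degrees of freedom = g - 1)."""
    df = _clean(times, events, group_labels)
    n_groups = df["group"].nunique()
    if n_groups < 2:
        raise ValidationError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), float(res.p_value), n_groups - 1


def stage_association(labels, stage, trend: bool = False) -> dict:
    """Subtype x stage contingency table with a chi-square independence test.

    ``trend=True`` runs the linear-by-linear association test
    M^2 = (N - 1) r^2 on the ordinal stage codes instead. Sparse 2x2 tables
    (any expected count < 5) fall back to Fisher's exact test, flagged.
    """
    df = pd.DataFrame({"subtype": np.asarray(labels), "stage": np.asarray(stage)})
    df = df.dropna()
    table = pd.crosstab(df["subtype"], df["stage"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("need >= 2 subtypes and >= 2 observed stages")
    if trend:
        sub_codes = pd.factorize(df["subtype"], sort=True)[0].astype(float)
        stage_codes = pd.Categorical(df["stage"], ordered=True).codes.astype(float)
        r = np.corrcoef(sub_codes, stage_codes)[0, 1]
        m2 = (len(df) - 1) * r ** 2
        p = float(stats.chi2.sf(m2, df=1))
        return {"table": table, "statistic": float(m2), "p_value": p,
                "method": "linear-by-linear trend", "flag": ""}
    chi2, p, dof, expected = stats.chi2_contingency(table)
    flag = ""
    if (expected < 5).any():
        flag = "sparse"
        if table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            return {"table": table, "statistic": float(chi2), "p_value": float(p),
                    "method": "fisher-exact", "flag": "sparse-exact"}
    return {"table": table, "statistic": float(chi2), "p_value": float(p),
            "method": "chi-square", "flag": flag}


def size_association(labels, sizes) -> dict:
    """Kruskal-Wallis comparison of tumor size across subtypes."""
    df = pd.DataFrame({"subtype": np.asarray(labels),
                       "size": np.asarray(sizes, dtype=float)}).dropna()
    groups = [g["size"].to_numpy() for _, g in df.groupby("subtype")]
    if len(groups) < 2:
        raise ValidationError("need >= 2 subtypes")
    h, p = stats.kruskal(*groups)
    return {"statistic": float(h), "p_value": float(p), "method": "kruskal-wallis"}
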