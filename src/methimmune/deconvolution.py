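"""Constrained least-squares deconvolution of bulk methylomes.

Each bulk sample's marker-gene beta vector y is modeled as a convex-ish
combination of the signature columns,

    y_i = sum_j a_j x_ij + eps_i,    minimize sum_i eps_i^2
    subject to  a_j >= 0,  sum_j a_j <= 1,

where a_j is the infiltration fraction of immune cell type j and the slack
1 - sum_j a_j is the non-immune content of the sample. The bound a_j <= 1 is
implied by nonnegativity plus the sum constraint.

The quadratic program is solved exactly by face enumeration: the global
optimum of a convex QP lies on some face of the feasible polytope and, on
that face, coincides with the least-squares minimizer over the face's affine
hull. With J cell types there are 2^J choices of zeroed coordinates times two
states of the sum constraint; every face's affine minimizer is computed and
the feasible one with the lowest objective is returned. Exact and fast for
the small J (7 immune cell types) this model targets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import BetaMatrix, SampleSheet, ValidationError
from .markers import SignatureMatrix

__all__ = [
    "FractionMatrix",
    "GroupComparison",
    "solve_fractions",
    "deconvolve_sample",
    "deconvolve_matrix",
    "apply_threshold",
    "compare_groups",
]

_MAX_TYPES = 14  # face enumeration is 2^J; guard against misuse


@dataclass
class FractionMatrix:
    """Sample x cell-type infiltration fractions with diagnostics.

    ``fractions`` is the reported matrix (entries below ``threshold`` zeroed,
    no renormalization); ``raw`` keeps the untouched QP solutions; ``rss`` is
    the per-sample residual sum of squares.
    """

    fractions: pd.DataFrame
    raw: pd.DataFrame
    rss: pd.Series
    threshold: float
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if ((arr < 0) | (arr > 1)).any():
            raise ValidationError("fractions must lie in [0, 1]")
        if (arr.sum(axis=1) > 1 + 1e-8).any():
            raise ValidationError("per-sample fraction sums must be <= 1")
        nonzero = arr[arr > 0]
        if self.threshold > 0 and len(nonzero) and nonzero.min() < self.threshold - 1e-12:
            raise ValidationError("reported fractions must be 0 or >= threshold")

    @property
    def sample_ids(self) -> list:
        return list(self.fractions.index)

    @property
    def cell_types(self) -> list:
        return list(self.fractions.columns)

    @property
    def fraction_sum(self) -> pd.Series:
        return self.fractions.sum(axis=1).rename("fraction_sum")

    def to_frame(self) -> pd.DataFrame:
        out = self.fractions.copy()
        out["fraction_sum"] = self.fraction_sum
        out["rss"] = self.rss
        return out.rename_axis("sample_id")


# ---------------------------------------------------------------------------
# QP core
# ---------------------------------------------------------------------------

def solve_fractions(y: np.ndarray, X: np.ndarray, sum_bound: float = 1.0,
                    tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """argmin ||y - X a||^2  s.t.  a >= 0, sum(a) <= sum_bound.

    Returns (a, residuals). Exact global optimum by face enumeration; handles
    rank-deficient X (minimizers computed with pinv, feasibility still checked).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError(
            f"dimension mismatch: y has {y.shape}, X has {X.shape}")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValidationError("missing values in deconvolution inputs")
    J = X.shape[1]
    if J > _MAX_TYPES:
        raise ValidationError(f"face enumeration supports <= {_MAX_TYPES} cell types")

    XtX = X.T @ X
    Xty = X.T @ y
    best_a, best_obj = np.zeros(J), float(y @ y)  # the a = 0 vertex

    for r in range(1, J + 1):
        for free in itertools.combinations(range(J), r):
            F = list(free)
            A = XtX[np.ix_(F, F)]
            b = Xty[F]
            # sum constraint inactive: unconstrained minimizer on the face
            a_f = _psolve(A, b)
            cand = _assemble(J, F, a_f)
            s = cand.sum()
            if (cand >= -tol).all() and s <= sum_bound + tol:
                best_a, best_obj = _keep_best(y, X, cand, best_a, best_obj, tol)
            # sum constraint active: minimize on {sum a_F = sum_bound}
            k = len(F)
            K = np.zeros((k + 1, k + 1))
            K[:k, :k] = A
            K[:k, k] = 0.5
            K[k, :k] = 1.0
            rhs = np.concatenate([b, [sum_bound]])
            sol = _psolve(K, rhs)
            cand = _assemble(J, F, sol[:k])
            if (cand >= -tol).all():
                best_a, best_obj = _keep_best(y, X, cand, best_a, best_obj, tol)

    a = np.clip(best_a, 0.0, None)
    if a.sum() > sum_bound:
        a *= sum_bound / a.sum()
    return a, y - X @ a


def _psolve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A) @ b


def _assemble(J: int, free: list, vals: np.ndarray) -> np.ndarray:
    a = np.zeros(J)
    a[free] = vals
    return a


def _keep_best(y, X, cand, best_a, best_obj, tol):
    r = y - X @ cand
    obj = float(r @ r)
    if obj < best_obj or (abs(obj - best_obj) <= tol and cand.sum() < best_a.sum()):
        return cand, min(obj, best_obj)
    return best_a, best_obj


def deconvolve_sample(y, X: SignatureMatrix | pd.DataFrame | np.ndarray
                      ) -> tuple[np.ndarray, dict]:
    """Solve one sample's QP; returns (fractions, diagnostics).

    Diagnostics: residual vector, residual sum of squares, fraction sum, and
    a rank-deficiency flag (a warning is issued but a solution is still
    returned — the QP stays feasible)."""
    if isinstance(X, SignatureMatrix):
        X = X.means
    Xarr = np.asarray(X, dtype=float)
    yarr = np.asarray(y, dtype=float).ravel()
    rank_deficient = np.linalg.matrix_rank(Xarr) < Xarr.shape[1]
    if rank_deficient:
        warnings.warn("signature matrix is rank deficient; solution is one of "
                      "several minimizers", RuntimeWarning, stacklevel=2)
    a, resid = solve_fractions(yarr, Xarr)
    return a, {
        "residuals": resid,
        "rss": float(resid @ resid),
        "fraction_sum": float(a.sum()),
        "rank_deficient": bool(rank_deficient),
    }


def apply_threshold(raw: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Zero out fractions below the reporting threshold; no renormalization.
    Idempotent, and never increases any fraction."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    return raw.where(raw >= threshold, 0.0)


def deconvolve_matrix(samples: BetaMatrix, signature: SignatureMatrix,
                      threshold: float = 0.01) -> FractionMatrix:
    """Per-sample QP over the signature's marker genes.

    An infiltration value is reported only when it exceeds ``threshold``
    (default 0.01); smaller estimates are set to zero in the reported matrix
    and kept in the raw diagnostics.
    """
    missing = [g for g in signature.genes if g not in samples.values.index]
    if missing:
        raise ValidationError(f"marker genes missing from sample matrix: {missing[:10]}")
    Y = samples.values.loc[signature.genes]
    if Y.isna().to_numpy().any():
        bad = Y.columns[Y.isna().any(axis=0)].tolist()
        raise ValidationError(f"missing marker betas in samples: {bad[:10]}")
    X = signature.means.to_numpy()
    rank_deficient = np.linalg.matrix_rank(X) < X.shape[1]
    if rank_deficient:
        warnings.warn("signature matrix is rank deficient", RuntimeWarning,
                      stacklevel=2)
    sols, rss = [], []
    for sid in Y.columns:
        a, resid = solve_fractions(Y[sid].to_numpy(), X)
        sols.append(a)
        rss.append(float(resid @ resid))
    raw = pd.DataFrame(np.vstack(sols), index=list(Y.columns),
                       columns=signature.cell_types)
    raw.index.name = "sample_id"
    return FractionMatrix(
        fractions=apply_threshold(raw, threshold),
        raw=raw,
        rss=pd.Series(rss, index=raw.index, name="rss"),
        threshold=threshold,
        rank_deficient=rank_deficient,
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    tumor_vs_normal: pd.DataFrame   # per (cancer, cell type) Welch t
    across_cancers: pd.DataFrame    # per cell type one-way ANOVA over tumors


def compare_groups(fractions: FractionMatrix, sheet: SampleSheet,
                   alpha: float = 0.05, correction: str = "fdr_bh"
                   ) -> GroupComparison:
    """Tumor-vs-normal location tests per (cancer, cell type), and a one-way
    ANOVA per cell type across cancer types (tumor samples only)."""
    frac = fractions.fractions
    meta = sheet.table.loc[[s for s in frac.index if s in sheet.table.index]]
    rows = []
    for cancer, sub in meta.groupby("cancer_type", sort=True):
        tum = frac.loc[sub.loc[sub["group"] == "tumor", "sample_id"]]
        nor = frac.loc[sub.loc[sub["group"] == "normal", "sample_id"]]
        for ct in frac.columns:
            if len(tum) < 2 or len(nor) < 2:
                rows.append({"cancer_type": cancer, "cell_type": ct,
                             "mean_tumor": tum[ct].mean() if len(tum) else np.nan,
                             "mean_normal": nor[ct].mean() if len(nor) else np.nan,
                             "t": np.nan, "p_value": np.nan,
                             "direction": "nochange", "flag": "skipped"})
                continue
            t, p = _welch(tum[ct].to_numpy(), nor[ct].to_numpy())
            rows.append({"cancer_type": cancer, "cell_type": ct,
                         "mean_tumor": tum[ct].mean(), "mean_normal": nor[ct].mean(),
                         "t": t, "p_value": p, "direction": "", "flag": ""})
    tn = pd.DataFrame(rows)
    tested = tn["p_value"].notna()
    tn["q_value"] = np.nan
    if tested.any():
        tn.loc[tested, "q_value"] = multipletests(tn.loc[tested, "p_value"],
                                                  method=correction)[1]
    sig = tested & (tn["q_value"] < alpha)
    tn.loc[sig, "direction"] = np.where(
        tn.loc[sig, "mean_tumor"] > tn.loc[sig, "mean_normal"], "increase", "decrease")
    tn.loc[tested & ~sig, "direction"] = "nochange"

    tumors = meta[meta["group"] == "tumor"]
    arows = []
    for ct in frac.columns:
        groups = [frac.loc[sub["sample_id"], ct].to_numpy()
                  for _, sub in tumors.groupby("cancer_type") if len(sub) >= 2]
        if len(groups) < 2:
            arows.append({"cell_type": ct, "F": np.nan, "p_value": np.nan,
                          "flag": "skipped"})
            continue
        F, p = stats.f_oneway(*groups)
        arows.append({"cell_type": ct, "F": float(F), "p_value": float(p), "flag": ""})
    an = pd.DataFrame(arows)
    tested = an["p_value"].notna()
    an["q_value"] = np.nan
    if tested.any():
        an.loc[tested, "q_value"] = multipletests(an.loc[tested, "p_value"],
                                                  method=correction)[1]
    return GroupComparison(tumor_vs_normal=tn, across_cancers=an)


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.var(x) == 0 and np.var(y) == 0:
        return (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
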