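"""Immune subtyping by consensus k-means on infiltration fractions.

Samples of one cancer are clustered repeatedly (k-means on subsamples); the
consensus matrix records how often each sample pair lands in the same cluster
when both are drawn. The number of clusters is chosen from the empirical CDF
of consensus values: the area under the CDF grows as k increases, and the
chosen k is the smallest one beyond which the relative area gain stays below
a stability tolerance (diminishing-returns rule). Fractions are clustered on
their native [0, 1] scale without standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .data_io import SampleSheet, ValidationError

__all__ = [
    "KMeansResult",
    "ConsensusResult",
    "kmeans_partition",
    "consensus_cluster",
    "cdf_area",
    "select_k",
    "embed_tsne",
    "subtype_cohort",
]


@dataclass
class KMeansResult:
    labels: np.ndarray       # 1..k
    centroids: np.ndarray
    inertia: float           # sum of squared distances to assigned centroids


@dataclass
class ConsensusResult:
    k_range: list
    consensus: dict                      # k -> sample x sample co-clustering freq
    areas: dict                          # k -> area under the consensus CDF
    never_cosampled: dict                # k -> count of undefined pairs
    chosen_k: int
    labels: pd.Series                    # final partition, clusters 1..chosen_k
    inertia: float
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, M in self.consensus.items():
            finite = np.isfinite(M)
            if not np.allclose(M[finite], M.T[finite]):
                raise ValidationError("consensus matrices must be symmetric")
            if not np.allclose(np.diag(M), 1.0):
                raise ValidationError("consensus diagonal must be 1")
            vals = M[finite]
            if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
                raise ValidationError("consensus values must lie in [0, 1]")
        if self.chosen_k not in self.k_range:
            raise ValidationError("chosen k outside the scanned range")


def _as_array(points) -> tuple[np.ndarray, list]:
    if isinstance(points, pd.DataFrame):
        return points.to_numpy(dtype=float), list(points.index)
    arr = np.asarray(points, dtype=float)
    return arr, list(range(len(arr)))


def kmeans_partition(points, k: int, seed: int | None = None,
                     n_init: int = 10) -> KMeansResult:
    """Seeded k-means++ / Lloyd partition minimizing the within-cluster sum of
    squared Euclidean distances J = sum_c sum_{x in c} ||x - mu_c||^2."""
    X, _ = _as_array(points)
    n = len(X)
    if not 2 <= k <= n:
        raise ValidationError(f"need n >= k >= 2, got n={n}, k={k}")
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < k:
        raise ValidationError(
            f"only {n_distinct} distinct points for k={k}; clusters would be empty")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=_to_state(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        labels = km.fit_predict(X)
    return KMeansResult(labels=labels + 1, centroids=km.cluster_centers_,
                        inertia=float(km.inertia_))


def _to_state(seed) -> int | None:
    return None if seed is None else int(seed) % (2 ** 31)


def consensus_cluster(points, k_range: Sequence[int] = range(2, 21),
                      n_resamples: int = 100, subsample_fraction: float = 0.8,
                      seed: int | None = None,
                      select_tolerance: float = 0.1) -> ConsensusResult:
    """Consensus k-means over subsampled runs, with CDF-area model selection.

    For each k, ``n_resamples`` k-means runs on random subsamples accumulate
    consensus(i, j) = (# times i, j co-clustered) / (# times both drawn).
    Pairs never co-sampled are excluded from the CDF and counted.
    """
    X, ids = _as_array(points)
    n = len(X)
    if not 0 < subsample_fraction <= 1:
        raise ValidationError("subsample_fraction must be in (0, 1]")
    m = max(2, int(round(subsample_fraction * n)))
    k_range = [k for k in k_range if 2 <= k <= n - 1] or [2]
    if m < max(k_range):
        raise ValidationError("subsample smaller than the largest k")

    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    consensus, areas, undefined = {}, {}, {}
    for k in k_range:
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for r in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
            sub = X[idx]
            if len(np.unique(sub, axis=0)) < k:
                continue  # degenerate draw; resample contributes nothing
            res = kmeans_partition(sub, k, seed=int(rng.integers(2 ** 31)), n_init=1)
            same = res.labels[:, None] == res.labels[None, :]
            together[np.ix_(idx, idx)] += same
            cosampled[np.ix_(idx, idx)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(cosampled > 0, together / np.maximum(cosampled, 1), np.nan)
        np.fill_diagonal(M, 1.0)
        iu = np.triu_indices(n, 1)
        vals = M[iu]
        undefined[k] = int(np.isnan(vals).sum())
        consensus[k] = M
        areas[k] = cdf_area(vals[np.isfinite(vals)])

    chosen = select_k(areas, tolerance=select_tolerance)
    final = kmeans_partition(X, chosen, seed=_to_state(seed), n_init=10)
    return ConsensusResult(
        k_range=list(k_range), consensus=consensus, areas=areas,
        never_cosampled=undefined, chosen_k=chosen,
        labels=pd.Series(final.labels, index=ids, name="cluster"),
        inertia=final.inertia, sample_ids=ids)


def cdf_area(values: np.ndarray) -> float:
    """Exact area under the empirical CDF of consensus values on [0, 1]."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        return 0.0
    uniq, counts = np.unique(v, return_counts=True)
    F = np.cumsum(counts) / len(v)
    edges = np.concatenate([uniq, [1.0]])
    widths = np.diff(edges)
    return float((F * widths).sum())


def select_k(areas: Mapping[int, float], tolerance: float = 0.1) -> int:
    """Smallest k after which the relative CDF-area increase stays below
    ``tolerance`` (the flat part of the area curve); falls back to the largest
    scanned k when the curve never flattens."""
    ks = sorted(areas)
    if len(ks) < 2:
        return ks[0]
    delta = {}
    for prev, k in zip(ks, ks[1:]):
        a_prev = areas[prev]
        delta[k] = (areas[k] - a_prev) / a_prev if a_prev > 0 else np.inf
    drops = [d for d in delta.values() if d < -tolerance]
    if drops:
        warnings.warn(f"consensus CDF area decreased by up to {min(drops):.3f}; "
                      "the diminishing-returns rule is still applied", RuntimeWarning)
    for k in ks[:-1]:
        nxt = ks[ks.index(k) + 1]
        if delta[nxt] < tolerance:
            return k
    return ks[-1]


def embed_tsne(points, seed: int | None = None,
               perplexity: float | None = None) -> pd.DataFrame:
    """2-D t-SNE embedding for visualization only; nothing downstream depends
    on the coordinates."""
    X, ids = _as_array(points)
    n = len(X)
    if n < 5:
        raise ValidationError("t-SNE embedding needs >= 5 samples")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    ts = TSNE(n_components=2, perplexity=perplexity, init="random",
              random_state=_to_state(seed))
    coords = ts.fit_transform(X)
    if not np.isfinite(coords).all():
        raise ValidationError("t-SNE produced non-finite coordinates")
    return pd.DataFrame(coords, index=ids, columns=["tsne1", "tsne2"])


def subtype_cohort(fractions, sheet: SampleSheet,
                   k_range: Sequence[int] = range(2, 21), n_resamples: int = 100,
                   subsample_fraction: float = 0.8, seed: int | None = None,
                   select_tolerance: float = 0.1
                   ) -> tuple[pd.Series, dict[str, ConsensusResult]]:
    """Consensus-cluster each cancer's tumor samples separately.

    Returns per-sample labels ``"<cancer>:<cluster>"`` plus the per-cancer
    ConsensusResult objects.
    """
    frac = fractions.fractions if hasattr(fractions, "fractions") else fractions
    tumors = sheet.table[(sheet.table["group"] == "tumor")
                         & sheet.table["sample_id"].isin(frac.index)]
    root = np.random.SeedSequence(seed)
    labels = {}
    results: dict[str, ConsensusResult] = {}
    cancers = sorted(tumors["cancer_type"].unique())
    child = {c: int(s.generate_state(1)[0] % (2 ** 31))
             for c, s in zip(cancers, root.spawn(len(cancers)))}
    for cancer in cancers:
        ids = tumors.loc[tumors["cancer_type"] == cancer, "sample_id"].tolist()
        res = consensus_cluster(frac.loc[ids], k_range=k_range,
                                n_resamples=n_resamples,
                                subsample_fraction=subsample_fraction,
                                seed=child[cancer],
                                select_tolerance=select_tolerance)
        results[cancer] = res
        for sid, lab in res.labels.items():
            labels[sid] = f"{cancer}:{lab}"
    order = [s for s in frac.index if s in labels]
    return pd.Series({s: labels[s] for s in order}, name="subtype"), results
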