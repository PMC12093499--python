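"""Fingerprint clustering: feature selection, Manhattan/UPGMA hierarchical
clustering with cophenetic validation, k-means with elbow selection, classical
MDS, and cluster-of-clusters analysis.

Distances between seed areas are Manhattan (city-block) sums of absolute
trimmed-mean FBC differences over the selected target features — features
being the targets for which at least one seed showed significantly increased
connectivity. No feature scaling is applied by default: the clustering is
meant to reflect absolute FBC differences (a z-score switch exists).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .core import CohortTensor, Fingerprint, trimmed_mean
from .specificity import SpecificityMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterSolution:
    entity_ids: tuple[str, ...]
    labels: dict[str, int]
    k: int
    method: str  # "hierarchical" | "kmeans"
    linkage_tree: np.ndarray | None = field(default=None, repr=False)
    cophenetic_correlation: float | None = None
    inertia_curve: dict[int, float] | None = None
    mds_coords: dict[str, tuple[float, float]] | None = None

    def label_vector(self) -> np.ndarray:
        return np.asarray([self.labels[e] for e in self.entity_ids])


# ---------------------------------------------------------------------------
# features and distances
# ---------------------------------------------------------------------------

def select_features(spec: SpecificityMap) -> list[str]:
    """Targets for which at least one seed is flagged (target_specific or
    globally_elevated), in canonical column order."""
    flagged = spec.flagged()
    feats = [t for t in flagged.columns if bool(flagged[t].any())]
    if not feats:
        raise ValueError(
            "no target passed the specificity screen; increase effect sizes or cohort size"
        )
    return feats


def manhattan_matrix(
    fingerprint: Fingerprint,
    features: Sequence[str] | None = None,
    zscore: bool = False,
) -> pd.DataFrame:
    """Pairwise city-block distances between fingerprint rows over the
    selected feature columns."""
    vals = fingerprint.values
    if features is not None:
        missing = [f for f in features if f not in vals.columns]
        if missing:
            raise KeyError(f"features not in fingerprint: {missing}")
        vals = vals[list(features)]
    x = vals.to_numpy(dtype=float)
    if zscore:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="cityblock"))
    return pd.DataFrame(d, index=vals.index, columns=vals.index)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(dist: pd.DataFrame, k: int | None = None) -> ClusterSolution:
    """Average-linkage (UPGMA) tree on a precomputed distance matrix, with the
    cophenetic correlation as goodness of fit; optional cut into ``k`` groups.

    scipy breaks merge-height ties by scanning pairs in canonical (row-major
    condensed) order, i.e. the smallest canonical index pair merges first.
    """
    ids = tuple(dist.index)
    condensed = squareform(dist.to_numpy(dtype=float), checks=False)
    tree = hierarchy.linkage(condensed, method="average")
    if np.ptp(condensed) == 0:
        coph = 1.0 if condensed.size else float("nan")
    else:
        coph = float(hierarchy.cophenet(tree, condensed)[0])
    if k is None:
        k_eff = 1
        labels = {e: 1 for e in ids}
    else:
        flat = hierarchy.fcluster(tree, t=k, criterion="maxclust")
        labels = dict(zip(ids, (int(v) for v in flat)))
        k_eff = len(set(flat))
        if k_eff != k:
            logger.warning("requested k=%d but cut yields %d groups", k, k_eff)
    return ClusterSolution(
        entity_ids=ids,
        labels=labels,
        k=k_eff,
        method="hierarchical",
        linkage_tree=tree,
        cophenetic_correlation=coph,
    )


def cophenetic_distances(solution: ClusterSolution) -> pd.DataFrame:
    if solution.linkage_tree is None:
        raise ValueError("solution has no linkage tree")
    d = squareform(hierarchy.cophenet(solution.linkage_tree))
    return pd.DataFrame(d, index=solution.entity_ids, columns=solution.entity_ids)


# ---------------------------------------------------------------------------
# k-means + elbow
# ---------------------------------------------------------------------------

def _elbow_k(inertia: Mapping[int, float], candidates: Sequence[int]) -> int:
    """Elbow pick: maximiser of the discrete second difference of the
    log-inertia curve over ``candidates`` (each of which must have both
    neighbouring k in ``inertia``); ties go to the smallest k.

    The log makes the curvature statistic scale-free: a raw second difference
    is dominated by the large early drops of any steeply decreasing curve,
    whereas the log second difference peaks where the *relative* drop
    collapses — the elbow. It is also exactly invariant to global rescaling
    of the features."""
    ks = sorted(inertia)
    top = max(inertia.values())
    if top == 0:
        return min(candidates)
    eps = 1e-12 * top  # floor: inertia hits 0 when entities are duplicated
    logi = {k: np.log(max(v, eps)) for k, v in inertia.items()}
    pos = {k: i for i, k in enumerate(ks)}
    best_k, best_d2 = None, None
    for k in sorted(candidates):
        i = pos[k]
        d2 = logi[ks[i - 1]] - 2 * logi[ks[i]] + logi[ks[i + 1]]
        if best_d2 is None or d2 > best_d2:
            best_k, best_d2 = k, d2
    return best_k


def kmeans_elbow(
    fingerprint: Fingerprint,
    features: Sequence[str] | None = None,
    k_range: Iterable[int] = range(2, 9),
    rng_seed: int = 0,
    n_restarts: int = 50,
    zscore: bool = False,
) -> ClusterSolution:
    """k-means over a k range with elbow-based selection of the cluster count.

    Each k runs ``n_restarts`` greedy-k-means++ restarts from a fixed seed, so
    the result is deterministic. The optimal k maximises the second difference
    of the inertia curve (deterministic, reproducible elbow rule).
    """
    vals = fingerprint.values
    if features is not None:
        vals = vals[list(features)]
    x = vals.to_numpy(dtype=float)
    if zscore:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    ids = tuple(vals.index)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 1 or ks[-1] > len(ids) - 1:
        raise ValueError(f"k_range must lie within [1, {len(ids) - 1}]")
    if len(ks) == 1:
        warnings.warn("k range too small for an elbow; returning its single k")
        km = KMeans(n_clusters=ks[0], n_init=n_restarts,
                    random_state=int(rng_seed) % (2**31)).fit(x)
        labels = dict(zip(ids, (int(l) + 1 for l in km.labels_)))
        return ClusterSolution(entity_ids=ids, labels=labels, k=ks[0], method="kmeans",
                               inertia_curve={ks[0]: float(km.inertia_)})
    # pad the curve with k_min-1 and k_max+1 so that every requested k is a
    # candidate (otherwise an elbow at the boundary could never be chosen);
    # k=1 needs no fit (total dispersion)
    eval_ks = sorted(set(ks) | {ks[0] - 1, ks[-1] + 1} - {0})
    inertia: dict[int, float] = {}
    fits = {}
    for k in eval_ks:
        if k == 1:
            inertia[1] = float(((x - x.mean(axis=0)) ** 2).sum())
            continue
        km = KMeans(
            n_clusters=k, n_init=n_restarts, random_state=int(rng_seed) % (2**31)
        ).fit(x)
        inertia[k] = float(km.inertia_)
        fits[k] = km
    k_star = _elbow_k(inertia, ks)
    labels = dict(zip(ids, (int(l) + 1 for l in fits[k_star].labels_)))
    return ClusterSolution(
        entity_ids=ids,
        labels=labels,
        k=k_star,
        method="kmeans",
        inertia_curve=inertia,
    )


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

def mds_embed(dist: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Eigendecomposition of the double-centered squared-distance matrix;
    deterministic. Axis orientation is fixed by flipping each axis so the
    first entity with a nonzero coordinate on it is nonnegative.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[order], 0.0, None)
    lam[lam < 1e-9 * max(lam.max(), 1e-300)] = 0.0  # kill numerically-zero axes
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    for c in range(coords.shape[1]):
        col = coords[:, c]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, c] = -col
    cols = [f"mds{c + 1}" for c in range(n_components)]
    return pd.DataFrame(coords, index=dist.index, columns=cols)


# ---------------------------------------------------------------------------
# cluster-of-clusters
# ---------------------------------------------------------------------------

def cluster_fingerprint(
    cohort: CohortTensor, labels: Mapping[str, int | str], trim_fraction: float = 0.1
) -> Fingerprint:
    """Cluster-level fingerprint: per subject, average FBC over the member
    seeds of each cluster; then trimmed mean over subjects."""
    missing = [s for s in cohort.seed_ids if s not in labels]
    if missing:
        raise KeyError(f"labels missing for seeds: {missing}")
    groups: dict = {}
    for i, s in enumerate(cohort.seed_ids):
        groups.setdefault(labels[s], []).append(i)
    names = sorted(groups, key=lambda g: str(g))
    rows = []
    for g in names:
        per_subject = cohort.values[:, groups[g], :].mean(axis=1)  # (S, T)
        rows.append(trimmed_mean(per_subject, trim_fraction, axis=0))
    df = pd.DataFrame(rows, index=[str(g) for g in names], columns=list(cohort.target_ids))
    return Fingerprint(df, trim_fraction)


def cluster_cohort(
    cohort: CohortTensor, labels: Mapping[str, int | str], cohort_id: str | None = None
) -> CohortTensor:
    """Collapse the seed axis to clusters: per subject and target, the mean
    FBC over each cluster's member seeds. The result feeds the same
    specificity machinery as seed-level cohorts (cluster-level thresholds for
    replication analysis)."""
    missing = [s for s in cohort.seed_ids if s not in labels]
    if missing:
        raise KeyError(f"labels missing for seeds: {missing}")
    groups: dict = {}
    for i, s in enumerate(cohort.seed_ids):
        groups.setdefault(str(labels[s]), []).append(i)
    names = sorted(groups)
    vals = np.stack([cohort.values[:, groups[g], :].mean(axis=1) for g in names], axis=1)
    return CohortTensor(
        cohort_id=cohort_id or f"{cohort.cohort_id}-clusters",
        values=vals,
        subject_ids=cohort.subject_ids,
        seed_ids=tuple(names),
        target_ids=cohort.target_ids,
    )


def cluster_of_clusters(
    cl_fingerprint: Fingerprint,
    k_range: Iterable[int] = range(2, 5),
    rng_seed: int = 0,
    features: Sequence[str] | None = None,
) -> tuple[ClusterSolution, ClusterSolution]:
    """Re-run the clustering pipeline with clusters as entities: UPGMA tree
    (for similarity structure) and elbow-selected k-means, on the cluster-level
    fingerprint. Returns (hierarchical, kmeans) solutions."""
    if len(cl_fingerprint.row_ids) < 3:
        raise ValueError("cluster-of-clusters needs at least 3 clusters")
    dist = manhattan_matrix(cl_fingerprint, features)
    hier = hierarchical_cluster(dist)
    km = kmeans_elbow(cl_fingerprint, features, k_range, rng_seed)
    return hier, km


# ---------------------------------------------------------------------------
# recovery metric
# ---------------------------------------------------------------------------

def adjusted_rand(labels: Mapping[str, int | str], truth_labels: Mapping[str, int | str]) -> float:
    """Chance-corrected agreement (ARI) between two partitions of the same
    entity set; 1 for identical partitions, ~0 for independent ones."""
    if set(labels) != set(truth_labels):
        raise ValueError("partitions cover different entity sets")
    ents = sorted(labels)
    a = [labels[e] for e in ents]
    b = [truth_labels[e] for e in ents]
    return float(adjusted_rand_score(a, b))
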