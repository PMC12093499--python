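"""Whole-brain integrative connectivity and the connectivity-profile manifold.

An integrative hub, under this operationalisation, is not a parcel with a few
very strong connections but one maintaining *limited-strength* connections
with a broad array of areas. A connection from source parcel ``q`` into
target parcel ``t``'s connectivity profile is of limited strength when it
ranks within the top ``top_fraction`` (default 50%) of that profile after
excluding the strongest connections — those exceeding the target's bootstrap
threshold. A parcel's integrative fraction is the share of all other parcels
whose profiles contain it as a limited-strength connection; values are also
reported in decile-style bins (..., "65%-74%", ...).

``embed_profiles`` wraps a UMAP neighbor-graph embedding of whole-brain
trimmed-mean connectivity profiles, exporting both the 2-D coordinates and
the fuzzy-neighbor-graph edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import Fingerprint

#: Bin edges in percent: [0,5), [5,15), ..., [85,95), [95,100].
_BIN_EDGES = [0.0, 5.0] + [5.0 + 10.0 * i for i in range(1, 10)] + [100.000001]
_BIN_LABELS = ["0%-4%"] + [f"{int(lo)}%-{int(hi) - 1}%" for lo, hi in
                           zip(_BIN_EDGES[1:-2], _BIN_EDGES[2:-1])] + ["95%-100%"]


@dataclass(frozen=True)
class IntegrativeMap:
    limited_strength: pd.DataFrame = field(repr=False)  # bool, source rows x target cols
    fraction: pd.Series = field(repr=False)
    bins: pd.Series = field(repr=False)
    top_fraction: float


@dataclass(frozen=True)
class EmbeddingResult:
    coords: pd.DataFrame = field(repr=False)  # parcel x (umap1, umap2)
    edges: pd.DataFrame = field(repr=False)  # parcel_a, parcel_b, weight
    rng_seed: int


# ---------------------------------------------------------------------------
# limited-strength mask
# ---------------------------------------------------------------------------

def limited_strength_mask(
    whole_fingerprint: Fingerprint,
    target_thresholds: Mapping[str, float],
    top_fraction: float = 0.5,
    rank_scope: str = "remaining",
) -> pd.DataFrame:
    """Boolean source x target mask of limited-strength connections.

    Per target column: sources whose FBC exceeds the target's bootstrap
    threshold are excluded as "strongest"; among the remaining *connected*
    sources (FBC > 0; a zero edge is no connection) the top ``top_fraction``
    by FBC are marked True. ``rank_scope="remaining"`` counts
    the top fraction of the non-excluded sources (default);
    ``rank_scope="full"`` takes the top fraction of the full profile and then
    drops the excluded ones. Ties at the cut break by canonical parcel order.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if rank_scope not in ("remaining", "full"):
        raise ValueError(f"unknown rank_scope {rank_scope!r}")
    vals = whole_fingerprint.values
    ids = list(vals.index)
    if list(vals.columns) != ids:
        raise ValueError("whole-brain fingerprint must be square over one parcel set")
    missing = [t for t in ids if t not in target_thresholds]
    if missing:
        raise KeyError(f"missing threshold for target(s): {missing}")
    v = vals.to_numpy(dtype=float)
    n = len(ids)
    mask = np.zeros((n, n), dtype=bool)
    for j, t in enumerate(ids):
        col = v[:, j]
        sources = np.array([i for i in range(n) if i != j and col[i] > 0])
        if sources.size == 0:
            continue
        eligible = sources[col[sources] <= float(target_thresholds[t])]
        if rank_scope == "remaining":
            n_keep = int(np.floor(top_fraction * eligible.size))
            pool = eligible
        else:
            n_keep = int(np.floor(top_fraction * sources.size))
            pool = sources
        if n_keep == 0:
            continue
        # sort by descending FBC, ties by canonical (ascending) index
        order = pool[np.lexsort((pool, -col[pool]))]
        top = order[:n_keep]
        if rank_scope == "full":
            top = top[col[top] <= float(target_thresholds[t])]
        mask[top, j] = True
    return pd.DataFrame(mask, index=ids, columns=ids)


def integrative_score(mask: pd.DataFrame, top_fraction: float = 0.5) -> IntegrativeMap:
    """Integrative fraction per parcel: the share of other parcels' profiles
    in which it appears as a limited-strength connection (row sums of the
    source x target mask over n-1), with decile-style bin labels."""
    m = mask.to_numpy(dtype=bool)
    if m.shape[0] != m.shape[1]:
        raise ValueError("mask must be square")
    if np.diagonal(m).any():
        raise ValueError("mask diagonal must be False")
    n = m.shape[0]
    frac = m.sum(axis=1) / (n - 1)
    fraction = pd.Series(frac, index=mask.index)
    bins = pd.Series(
        pd.cut(frac * 100.0, bins=_BIN_EDGES, labels=_BIN_LABELS,
               right=False, include_lowest=True).astype(str),
        index=mask.index,
    )
    return IntegrativeMap(limited_strength=mask, fraction=fraction, bins=bins,
                          top_fraction=top_fraction)


def hub_overlap_map(mask: pd.DataFrame, roi_a: str, roi_b: str) -> pd.Series:
    """Categorise every parcel by which of two candidate hub areas appear in
    its limited-strength profile: only_a / only_b / both / none."""
    if roi_a == roi_b:
        raise ValueError("roi_a and roi_b must differ")
    for roi in (roi_a, roi_b):
        if roi not in mask.index:
            raise KeyError(f"unknown roi {roi!r}")
    a = mask.loc[roi_a].to_numpy(dtype=bool)
    b = mask.loc[roi_b].to_numpy(dtype=bool)
    cat = np.where(a & b, "both", np.where(a, "only_a", np.where(b, "only_b", "none")))
    out = pd.Series(cat, index=mask.columns)
    return out


# ---------------------------------------------------------------------------
# manifold embedding
# ---------------------------------------------------------------------------

def embed_profiles(
    whole_fingerprint: Fingerprint,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    rng_seed: int = 0,
) -> EmbeddingResult:
    """2-D UMAP embedding of whole-brain connectivity profiles.

    Deterministic under a fixed seed (single-threaded exact mode). The fuzzy
    neighbor graph's nonzero edge weights are exported as a long table.
    """
    import umap  # deferred: numba JIT import is slow

    x = whole_fingerprint.values.to_numpy(dtype=float)
    ids = list(whole_fingerprint.values.index)
    if len(ids) < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} parcels, got {len(ids)}")
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_components=2,
        random_state=int(rng_seed) % (2**31),
        force_approximation_algorithm=False,
    )
    coords = reducer.fit_transform(x)
    graph = reducer.graph_.tocoo()
    edges = pd.DataFrame(
        {
            "parcel_a": [ids[i] for i in graph.row],
            "parcel_b": [ids[j] for j in graph.col],
            "weight": graph.data.astype(float),
        }
    )
    edges = edges[edges["weight"] > 0].reset_index(drop=True)
    cdf = pd.DataFrame(coords, index=ids, columns=["umap1", "umap2"])
    return EmbeddingResult(coords=cdf, edges=edges, rng_seed=rng_seed)
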