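"""Connectome matrices, cohort tensors and trimmed-mean fingerprints.

The unit of input is a per-subject symmetric parcel-by-parcel matrix of fiber
bundle capacity (FBC, the summed intra-axonal cross-sectional area of the
streamlines linking two parcels; nonnegative, arbitrary scale). A cohort is a
stack of such matrices restricted to seed rows and target columns, and a
*fingerprint* summarises it as the trimmed-mean FBC per seed-target pair —
the trimming guards the average against the heavy-tailed, outlier-prone
distribution of tractography-derived edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasTable

ASYMMETRY_RTOL = 1e-6


@dataclass(frozen=True)
class SubjectConnectome:
    """One subject's symmetric, zero-diagonal, nonnegative FBC matrix.

    ``fbc`` is a DataFrame indexed by parcel id on both axes, in the canonical
    atlas order.
    """

    subject_id: str
    fbc: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        m = self.fbc.to_numpy()
        if not np.all(np.isfinite(m)):
            raise ValueError(f"{self.subject_id}: non-finite FBC entries")
        if (m < 0).any():
            raise ValueError(f"{self.subject_id}: negative FBC entries")
        if not np.allclose(m, m.T, rtol=0, atol=0):
            raise ValueError(f"{self.subject_id}: matrix not symmetric")
        if np.any(np.diagonal(m) != 0):
            raise ValueError(f"{self.subject_id}: nonzero diagonal")

    @property
    def parcel_ids(self) -> list[str]:
        return list(self.fbc.index)


@dataclass(frozen=True)
class CohortTensor:
    """Subjects x seeds x targets stack of FBC values for one cohort."""

    cohort_id: str
    values: np.ndarray = field(repr=False)  # (S, n_seeds, n_targets), float64
    subject_ids: tuple[str, ...]
    seed_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.subject_ids), len(self.seed_ids), len(self.target_ids)):
            raise ValueError("tensor shape inconsistent with id lists")
        if not np.all(np.isfinite(v)) or (v < 0).any():
            raise ValueError("cohort tensor must be finite and nonnegative")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass(frozen=True)
class Fingerprint:
    """Seed (or cluster) x target matrix of trimmed-mean FBC."""

    values: pd.DataFrame = field(repr=False)
    trim_fraction: float = 0.1

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# trimmed mean
# ---------------------------------------------------------------------------

def trimmed_mean(values, trim_fraction: float = 0.1, axis=None):
    """Mean after discarding ``floor(n * trim_fraction)`` observations from
    each tail.

    ``trim_fraction`` is the fraction removed from *each* tail and must lie in
    ``[0, 0.5)``. With ``trim_fraction == 0`` this is the arithmetic mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("trimmed_mean of empty input")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    return stats.trim_mean(arr, trim_fraction, axis=axis)


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def load_subject_matrix(path, atlas: AtlasTable, subject_id: str | None = None) -> SubjectConnectome:
    """Read a subject's FBC matrix from TSV (parcel-id header row and first
    column), reindex to canonical atlas order, symmetrize and zero the diagonal.

    Asymmetry up to a relative tolerance of 1e-6 is treated as floating-point
    I/O noise and resolved as ``(M + M.T) / 2``; larger asymmetry is an error
    (it usually indicates a transposition or indexing bug upstream).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    ids = atlas.parcel_ids
    if set(df.index) != set(ids) or set(df.columns) != set(ids):
        missing = (set(ids) - set(df.index)) | (set(ids) - set(df.columns))
        raise ValueError(f"matrix parcels do not match atlas; missing: {sorted(missing)}")
    df = df.loc[ids, ids]
    m = df.to_numpy(dtype=float)
    if (m < 0).any():
        raise ValueError("negative FBC entry in matrix")
    scale = np.abs(m).max()
    if scale > 0 and np.abs(m - m.T).max() > ASYMMETRY_RTOL * scale:
        raise ValueError("matrix asymmetric beyond tolerance")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    sid = subject_id if subject_id is not None else _stem(path)
    return SubjectConnectome(sid, pd.DataFrame(m, index=ids, columns=ids))


def write_subject_matrix(conn: SubjectConnectome, path) -> None:
    conn.fbc.to_csv(path, sep="\t", float_format="%.17g")


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base


# ---------------------------------------------------------------------------
# hemisphere combination
# ---------------------------------------------------------------------------

def combine_hemispheres(
    conn: SubjectConnectome, atlas: AtlasTable, mode: str = "mean"
) -> SubjectConnectome:
    """Merge homologous L/R parcels into one parcel per base name.

    Each merged edge (A, B) aggregates the four homologous hemispheric edges
    A_L-B_L, A_L-B_R, A_R-B_L, A_R-B_R with the chosen ``mode`` (``mean``
    keeps the FBC scale comparable across cohorts; ``sum`` pools edge mass).
    The merged self-edge is set to zero.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    merged = atlas.merge_hemispheres()
    t = atlas.table
    names = merged.table["parcel_name"].tolist()
    pos = {pid: i for i, pid in enumerate(conn.fbc.index)}
    li, ri = [], []
    for name in names:
        g = t.loc[t["parcel_name"] == name]
        left = g.loc[g["hemisphere"] == "L", "parcel_id"]
        right = g.loc[g["hemisphere"] == "R", "parcel_id"]
        if len(left) != 1 or len(right) != 1:
            raise ValueError(f"unpaired hemispheric parcel: {name}")
        li.append(pos[left.iloc[0]])
        ri.append(pos[right.iloc[0]])
    m = conn.fbc.to_numpy(dtype=float)
    li = np.asarray(li)
    ri = np.asarray(ri)
    stackedsum = (
        m[np.ix_(li, li)] + m[np.ix_(li, ri)] + m[np.ix_(ri, li)] + m[np.ix_(ri, ri)]
    )
    out = stackedsum / 4.0 if mode == "mean" else stackedsum
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    ids = merged.parcel_ids
    return SubjectConnectome(conn.subject_id, pd.DataFrame(out, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# cohort assembly and fingerprints
# ---------------------------------------------------------------------------

def assemble_cohort(
    connectomes: Sequence[SubjectConnectome],
    atlas: AtlasTable,
    seeds: Iterable[str] | None = None,
    targets: Iterable[str] | None = None,
    cohort_id: str = "cohort",
) -> CohortTensor:
    """Stack subject matrices into a subjects x seeds x targets tensor.

    ``seeds`` defaults to the atlas seed flags; ``targets`` defaults to all
    non-seed parcels (a seed's self-edge is undefined in a tractogram-derived
    matrix, so seeds are excluded from the default target axis; pass
    ``targets`` explicitly to include them — self-edges are then carried as
    zero from the matrix diagonal).
    """
    if len(connectomes) < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    seed_ids = tuple(seeds) if seeds is not None else tuple(atlas.seed_ids)
    if not seed_ids:
        raise ValueError("seed list is empty")
    target_ids = tuple(targets) if targets is not None else tuple(atlas.target_ids)
    ids = atlas.parcel_ids
    ref = set(ids)
    pos = {pid: i for i, pid in enumerate(ids)}
    si = np.asarray([pos[s] for s in seed_ids])
    ti = np.asarray([pos[t] for t in target_ids])
    vals = np.empty((len(connectomes), len(seed_ids), len(target_ids)))
    for k, conn in enumerate(connectomes):
        if set(conn.fbc.index) != ref:
            raise ValueError(f"subject {conn.subject_id}: parcel set mismatch")
        m = conn.fbc.to_numpy(dtype=float)
        vals[k] = m[np.ix_(si, ti)]
    return CohortTensor(
        cohort_id=cohort_id,
        values=vals,
        subject_ids=tuple(c.subject_id for c in connectomes),
        seed_ids=seed_ids,
        target_ids=target_ids,
    )


def fingerprint_matrix(cohort: CohortTensor, trim_fraction: float = 0.1) -> Fingerprint:
    """Trimmed-mean FBC per seed-target pair, averaged over subjects."""
    vals = trimmed_mean(cohort.values, trim_fraction, axis=0)
    df = pd.DataFrame(vals, index=list(cohort.seed_ids), columns=list(cohort.target_ids))
    return Fingerprint(df, trim_fraction)


def whole_brain_fingerprint(
    connectomes: Sequence[SubjectConnectome], trim_fraction: float = 0.1
) -> Fingerprint:
    """Parcel x parcel trimmed-mean FBC matrix over a cohort (every parcel
    treated as both source and target); the input to the integrative-
    connectivity analysis."""
    if len(connectomes) < 2:
        raise ValueError("need at least 2 subjects")
    ids = connectomes[0].parcel_ids
    stack = np.stack([c.fbc.loc[ids, ids].to_numpy(dtype=float) for c in connectomes])
    vals = trimmed_mean(stack, trim_fraction, axis=0)
    return Fingerprint(pd.DataFrame(vals, index=ids, columns=ids), trim_fraction)
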