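"""Cluster-vs-cluster contrasts and cross-cohort replication concordance.

For each target (single parcel or functional target group), the cluster with
the highest mean per-subject FBC is tested one-sidedly against every other
cluster. Because p values alone are uninformative at cohort sizes of several
hundred subjects, a contrast only *passes* when the top cluster beats every
competitor at ``alpha`` AND the effect size gate holds: Cohen's d with a
bootstrap confidence interval whose lower bound exceeds ``d_min`` (default
0.8, a large effect). A looser point-estimate-only gate (d > d_min) is
available via ``ci_rule=False``.

Replication concordance compares two cohorts' specificity maps: a
cluster-target connection is concordant when it exceeds the bootstrap
threshold in both cohorts or in neither, and discordant when in exactly one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasTable
from .core import CohortTensor
from .specificity import SpecificityMap

logger = logging.getLogger(__name__)

#: Functional/anatomical grouping of target areas (frontal, Broca, orbito-
#: frontal, motor, auditory, visual and somatosensory systems), matching the
#: parcel names of the study-structured synthetic atlas.
TARGET_GROUPS: dict[str, tuple[str, ...]] = {
    "Frontal": (
        "Frontal_to_Temporal_I", "Frontal_to_Temporal_II", "Frontal_I", "Frontal_II",
        "IFS1", "IFS2", "IF3", "IFS4", "IFJ1", "IFJ2", "8v2", "8v1", "Fp1", "Fp2",
        "OP5", "OP6", "OP7", "OP8", "OP9", "8d2", "8d1",
    ),
    "Broca": ("44", "45"),
    "Orbitofrontal": ("Fo1", "Fo2", "Fo3", "Fo4", "Fo5", "Fo6", "Fo7"),
    "Motor": ("6d1", "6d2", "6ma", "6d3", "6mp", "4p", "4a"),
    "Auditory": ("TE1.0", "TE1.1", "TE1.2"),
    "Primary visual": ("hOc1", "hOc2"),
    "Higher visual": ("hOc3v", "hOc3d", "hOc4v", "hOc4d", "hOc4lp", "hOc4Ia", "hOc5", "hOc6"),
    "Primary somatosensory": ("1", "2", "3a", "3b"),
    "Secondary somatosensory": ("OP1", "OP2", "OP3", "OP4"),
}


def validate_target_groups(
    groups: Mapping[str, Sequence[str]], atlas: AtlasTable
) -> dict[str, tuple[str, ...]]:
    """Check a target grouping against the atlas: unknown parcels are a hard
    error, overlap between groups only a warning."""
    parcels = set(atlas.parcel_ids)
    seen: dict[str, str] = {}
    out = {}
    for name, members in groups.items():
        unknown = [m for m in members if m not in parcels]
        if unknown:
            raise ValueError(f"target group {name!r}: parcels not in atlas: {unknown}")
        for m in members:
            if m in seen:
                logger.warning("parcel %s appears in groups %s and %s", m, seen[m], name)
            seen[m] = name
        out[name] = tuple(members)
    return out


@dataclass(frozen=True)
class ContrastResult:
    target: str
    top_cluster: str
    table: pd.DataFrame = field(repr=False)  # competitor, p, d, d_ci_low, d_ci_high
    passed: bool
    alpha: float
    d_min: float


@dataclass(frozen=True)
class ConcordanceMap:
    """Per cluster-target concordance category between two cohorts."""

    categories: pd.DataFrame = field(repr=False)

    def counts(self) -> dict[str, int]:
        flat = self.categories.to_numpy().ravel()
        return {c: int((flat == c).sum()) for c in
                ("concordant_present", "concordant_absent", "discordant")}

    @property
    def discordant_fraction(self) -> float:
        c = self.counts()
        total = sum(c.values())
        return c["discordant"] / total if total else 0.0


# ---------------------------------------------------------------------------
# per-subject cluster values
# ---------------------------------------------------------------------------

def subject_cluster_fbc(
    cohort: CohortTensor,
    labels: Mapping[str, int | str],
    target_set: Sequence[str],
) -> pd.DataFrame:
    """Per-subject, per-cluster mean FBC over (member seeds) x (targets in
    the set); subjects as rows, clusters as columns."""
    if len(target_set) == 0:
        raise ValueError("empty target set")
    missing = [s for s in cohort.seed_ids if s not in labels]
    if missing:
        raise KeyError(f"labels missing for seeds: {missing}")
    tpos = {t: j for j, t in enumerate(cohort.target_ids)}
    bad = [t for t in target_set if t not in tpos]
    if bad:
        raise KeyError(f"targets not in cohort: {bad}")
    tj = [tpos[t] for t in target_set]
    groups: dict = {}
    for i, s in enumerate(cohort.seed_ids):
        groups.setdefault(str(labels[s]), []).append(i)
    names = sorted(groups)
    cols = {
        g: cohort.values[np.ix_(range(cohort.n_subjects), groups[g], tj)].mean(axis=(1, 2))
        for g in names
    }
    return pd.DataFrame(cols, index=list(cohort.subject_ids))


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

def cohens_d_ci(
    x,
    y,
    n_boot: int = 2000,
    rng_seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Cohen's d (pooled-SD standardised mean difference) with a percentile
    bootstrap confidence interval (independent resampling of both samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    d = _cohens_d(x, y)
    rng = np.random.default_rng(int(rng_seed) % (2**31))
    xi = rng.integers(0, x.size, size=(n_boot, x.size))
    yi = rng.integers(0, y.size, size=(n_boot, y.size))
    bx, by = x[xi], y[yi]
    mx, my = bx.mean(axis=1), by.mean(axis=1)
    vx, vy = bx.var(axis=1, ddof=1), by.var(axis=1, ddof=1)
    pooled = np.sqrt(((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        ds = (mx - my) / pooled
    ds = ds[np.isfinite(ds)]
    if ds.size == 0:
        raise ValueError("bootstrap produced no finite effect sizes")
    lo, hi = np.percentile(ds, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])
    return d, (float(lo), float(hi))


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = np.sqrt(((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    return float((x.mean() - y.mean()) / pooled)


# ---------------------------------------------------------------------------
# contrast test
# ---------------------------------------------------------------------------

def contrast_test(
    values: pd.DataFrame,
    target: str = "",
    alpha: float = 0.01,
    d_min: float = 0.8,
    rng_seed: int = 0,
    n_boot: int = 2000,
    ci_rule: bool = True,
    paired: bool = False,
) -> ContrastResult:
    """Test whether the cluster with the highest mean FBC significantly
    outperforms every other cluster for this target.

    One-sided Welch t-test (or paired t-test with ``paired=True``) of the top
    cluster against each competitor; the contrast passes only if every
    competitor is beaten at ``alpha`` with the effect-size gate satisfied
    (CI lower bound > ``d_min`` when ``ci_rule``, else d > ``d_min``).
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 clusters")
    means = values.mean(axis=0)
    top_mean = means.max()
    tied = [c for c in values.columns if means[c] == top_mean]
    if len(tied) > 1:
        logger.warning("tie for top cluster on %s: %s; picking first in canonical order",
                       target, tied)
    top = tied[0]
    x = values[top].to_numpy(dtype=float)
    rows = []
    passed = True
    for comp in values.columns:
        if comp == top:
            continue
        y = values[comp].to_numpy(dtype=float)
        if paired:
            t, p = stats.ttest_rel(x, y, alternative="greater")
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        d, (lo, hi) = cohens_d_ci(x, y, n_boot=n_boot, rng_seed=rng_seed)
        gate = lo > d_min if ci_rule else d > d_min
        ok = (p < alpha) and gate
        passed = passed and ok
        rows.append({"competitor": comp, "p": float(p), "d": d,
                     "d_ci_low": lo, "d_ci_high": hi, "beaten": ok})
    table = pd.DataFrame(rows)
    return ContrastResult(target=target, top_cluster=str(top), table=table,
                          passed=bool(passed), alpha=alpha, d_min=d_min)


def contrast_all_targets(
    cohort: CohortTensor,
    labels: Mapping[str, int | str],
    target_groups: Mapping[str, Sequence[str]],
    alpha: float = 0.01,
    d_min: float = 0.8,
    rng_seed: int = 0,
    n_boot: int = 2000,
    ci_rule: bool = True,
) -> list[ContrastResult]:
    """Run the gated contrast for every target group present in the cohort."""
    results = []
    avail = set(cohort.target_ids)
    for name, members in target_groups.items():
        present = [m for m in members if m in avail]
        if not present:
            logger.warning("target group %s has no parcels in cohort; skipped", name)
            continue
        vals = subject_cluster_fbc(cohort, labels, present)
        results.append(contrast_test(vals, name, alpha, d_min, rng_seed, n_boot, ci_rule))
    return results


# ---------------------------------------------------------------------------
# replication concordance
# ---------------------------------------------------------------------------

def replication_concordance(spec_a: SpecificityMap, spec_b: SpecificityMap) -> ConcordanceMap:
    """Categorise every (cluster, target) cell by agreement across cohorts:
    above-threshold in both / in neither (concordant) or in exactly one
    (discordant). Symmetric in cohort order."""
    if list(spec_a.levels.index) != list(spec_b.levels.index) or list(
        spec_a.levels.columns
    ) != list(spec_b.levels.columns):
        raise ValueError("specificity maps cover different cluster/target universes")
    a = spec_a.flagged().to_numpy()
    b = spec_b.flagged().to_numpy()
    cat = np.where(a & b, "concordant_present",
                   np.where(~a & ~b, "concordant_absent", "discordant"))
    return ConcordanceMap(
        categories=pd.DataFrame(cat, index=spec_a.levels.index, columns=spec_a.levels.columns)
    )
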