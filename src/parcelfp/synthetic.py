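"""Synthetic connectome cohorts with planted fingerprint structure.

Subject-level FBC matrices are not publicly deposited for the cohorts this
pipeline is designed around, so this module generates cohorts with the
statistical structure the analysis assumes, together with the ground truth
needed for recovery tests:

* log-normal edge weights (FBC is positive and right-skewed),
* whole-subject multiplicative outliers emulating tractography scale failures
  (the reason the pipeline summarises with a trimmed mean),
* groups of insular seed parcels sharing a target-affinity fingerprint
  (multiplicatively elevated FBC on a group-specific target set),
* an optional second cohort with globally rescaled FBC, emulating a
  replication data set acquired with a different protocol.

``make_paper_atlas`` builds the study-structured configuration: 16 insular
seed areas partitioned into six groups (three dorsal anterior, one ventral
anterior, two posterior), with e.g. the ventral anterior group connected to
orbitofrontal targets and the superior posterior group to auditory and
parietal-opercular targets, inside a 107-parcel merged-hemisphere inventory
(214 parcels at hemispheric granularity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import AtlasTable
from .core import SubjectConnectome

# ---------------------------------------------------------------------------
# study-structured inventory
# ---------------------------------------------------------------------------

INSULAR_SEEDS = (
    "Ia1", "Ia2", "Ia3",
    "Id1", "Id2", "Id3", "Id4", "Id5", "Id6", "Id7", "Id8", "Id9", "Id10",
    "Ig1", "Ig2", "Ig3",
)

GRANULARITY = {
    **{s: "agranular" for s in ("Ia1", "Ia2", "Ia3")},
    **{s: "dysgranular" for s in INSULAR_SEEDS if s.startswith("Id")},
    **{s: "granular" for s in ("Ig1", "Ig2", "Ig3")},
}

#: Six planted seed groups emulating the published cluster composition
#: (superior/inferior posterior, three dorsal anterior, one ventral anterior).
PAPER_SEED_GROUPS: dict[str, tuple[str, ...]] = {
    "dorsal_anterior_1": ("Id4", "Id5"),
    "dorsal_anterior_2": ("Id7", "Id8", "Id9"),
    "dorsal_anterior_3": ("Id6", "Ia1", "Ia2", "Ia3"),
    "ventral_anterior": ("Id10",),
    "superior_posterior": ("Ig1", "Ig2"),
    "inferior_middle_posterior": ("Id1", "Id2", "Id3", "Ig3"),
}

_FRONTAL_NONOPERC = (
    "Frontal_to_Temporal_I", "Frontal_to_Temporal_II", "Frontal_I", "Frontal_II",
    "IFS1", "IFS2", "IF3", "IFS4", "IFJ1", "IFJ2",
    "8v1", "8v2", "Fp1", "Fp2", "8d1", "8d2",
)

#: Group -> target-affinity set. Pairwise disjoint so that planted-group
#: recovery is well-posed; assignments follow the cluster-target pattern of
#: the study design (orbitofrontal <-> ventral anterior, auditory/parietal
#: operculum <-> superior posterior, visual/temporal <-> inferior-middle
#: posterior, opercular/somatosensory <-> dorsal anterior 1, Broca/frontal
#: operculum <-> dorsal anterior 2, remaining frontal <-> dorsal anterior 3).
PAPER_AFFINITY_TARGETS: dict[str, tuple[str, ...]] = {
    "dorsal_anterior_1": ("OP3", "OP4", "OP5", "OP6", "1", "2", "3a", "3b"),
    "dorsal_anterior_2": ("44", "45", "OP7", "OP8", "OP9"),
    "dorsal_anterior_3": _FRONTAL_NONOPERC,
    "ventral_anterior": ("Fo1", "Fo2", "Fo3", "Fo4", "Fo5", "Fo6", "Fo7"),
    "superior_posterior": ("TE1.0", "TE1.1", "TE1.2", "OP1", "OP2"),
    "inferior_middle_posterior": (
        "hOc1", "hOc2", "hOc3v", "hOc3d", "hOc4v", "hOc4d",
        "hOc4lp", "hOc4Ia", "hOc5", "hOc6", "TI",
    ),
}

_TARGET_REGIONS: list[tuple[str, str]] = (
    [(t, "frontal") for t in _FRONTAL_NONOPERC]
    + [(t, "frontal") for t in ("OP5", "OP6", "OP7", "OP8", "OP9")]
    + [(t, "frontal") for t in ("44", "45")]
    + [(t, "frontal") for t in ("Fo1", "Fo2", "Fo3", "Fo4", "Fo5", "Fo6", "Fo7")]
    + [(t, "frontal") for t in ("6d1", "6d2", "6ma", "6d3", "6mp", "4p", "4a")]
    + [(t, "temporal") for t in ("TE1.0", "TE1.1", "TE1.2", "TE2.1", "TE2.2", "TE3",
                                  "TI", "STS1", "STS2", "FG1", "FG2", "FG3", "FG4")]
    + [(t, "occipital") for t in ("hOc1", "hOc2", "hOc3v", "hOc3d", "hOc4v", "hOc4d",
                                   "hOc4lp", "hOc4Ia", "hOc5", "hOc6")]
    + [(t, "parietal") for t in ("1", "2", "3a", "3b", "OP1", "OP2", "OP3", "OP4",
                                  "5Ci", "5L", "5M", "7A", "7PC", "7M", "7P",
                                  "PF", "PFm", "PFt", "PFop", "PFcm", "PGa", "PGp",
                                  "hIP1", "hIP2")]
    + [(t, "limbic") for t in ("25", "33", "s24", "s32", "p24", "p32", "Ent")]
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth generating parameters of a synthetic cohort.

    FBC for a seed-target edge is log-normal with location
    ``baseline_loc + log(multiplier)`` when the target belongs to the seed's
    group affinity set, and ``baseline_loc`` otherwise; all non-seed edges are
    baseline. ``baseline_loc`` may be a single location or a per-parcel
    mapping (an edge's baseline is then the mean of its endpoints' locations;
    unlisted parcels fall back to the mapping's mean). A fixed fraction of subjects are whole-subject outliers whose
    entire matrix is multiplied by ``outlier_multiplier``. ``cohort_scale``
    rescales every value (used to emulate a cohort acquired at a globally
    elevated FBC scale).
    """

    group_of_seed: Mapping[str, str]
    affinity: Mapping[str, tuple[tuple[str, ...], float]]
    baseline_loc: float | Mapping[str, float] = float(np.log(10.0))
    baseline_scale: float = 0.4
    outlier_fraction: float = 0.05
    outlier_multiplier: float = 4.0
    cohort_scale: float = 1.0
    rng_seed: int = 0

    def validate(self, atlas: AtlasTable) -> None:
        parcels = set(atlas.parcel_ids)
        seeds = set(atlas.seed_ids)
        missing = seeds - set(self.group_of_seed)
        if missing:
            raise ValueError(f"seeds without a planted group: {sorted(missing)}")
        for g, (targets, mult) in self.affinity.items():
            if mult < 1.0:
                raise ValueError(f"group {g}: effect multiplier must be >= 1")
            unknown = set(targets) - parcels
            if unknown:
                raise ValueError(f"group {g}: affinity targets not in atlas: {sorted(unknown)}")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.outlier_multiplier <= 1:
            raise ValueError("outlier_multiplier must be > 1")
        if self.cohort_scale <= 0:
            raise ValueError("cohort_scale must be > 0")

    def with_multiplier(self, multiplier: float) -> "SyntheticTruth":
        """Copy of the truth with every group's effect multiplier replaced."""
        aff = {g: (targets, float(multiplier)) for g, (targets, _) in self.affinity.items()}
        return replace(self, affinity=aff)

    def true_labels(self) -> dict[str, str]:
        return dict(self.group_of_seed)

    def to_json(self) -> str:
        d = {
            "group_of_seed": dict(self.group_of_seed),
            "affinity": {g: [list(t), m] for g, (t, m) in self.affinity.items()},
            "baseline_loc": dict(self.baseline_loc)
            if isinstance(self.baseline_loc, Mapping) else self.baseline_loc,
            "baseline_scale": self.baseline_scale,
            "outlier_fraction": self.outlier_fraction,
            "outlier_multiplier": self.outlier_multiplier,
            "cohort_scale": self.cohort_scale,
            "rng_seed": self.rng_seed,
        }
        return json.dumps(d, indent=2)

    @staticmethod
    def from_json(text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["affinity"] = {g: (tuple(t), float(m)) for g, (t, m) in d["affinity"].items()}
        return SyntheticTruth(**d)


# ---------------------------------------------------------------------------
# atlas builders
# ---------------------------------------------------------------------------

def make_paper_atlas(
    split_hemispheres: bool = False,
    multiplier: float = 3.0,
    rng_seed: int = 0,
) -> tuple[AtlasTable, SyntheticTruth]:
    """Study-structured synthetic atlas plus the matching truth template.

    Returns a 107-parcel merged-hemisphere inventory (16 insular seeds in six
    planted groups, 91 targets with macro-region labels), or the 214-parcel
    hemispheric version with ``split_hemispheres=True``. ``multiplier`` is the
    planted affinity effect applied to every group.
    """
    rows = []
    for s in INSULAR_SEEDS:
        rows.append((s, s, "merged", "insular", True, GRANULARITY[s]))
    for t, region in _TARGET_REGIONS:
        rows.append((t, t, "merged", region, False, ""))
    df = pd.DataFrame(
        rows,
        columns=["parcel_id", "parcel_name", "hemisphere", "macro_region",
                 "is_insular_seed", "granularity"],
    )
    if split_hemispheres:
        halves = []
        for hemi, suffix in (("L", "_l"), ("R", "_r")):
            h = df.copy()
            h["parcel_id"] = h["parcel_id"] + suffix
            h["hemisphere"] = hemi
            halves.append(h)
        df = pd.concat(halves, ignore_index=True)
    atlas = AtlasTable(df)

    group_of_seed = {
        seed: group for group, seeds in PAPER_SEED_GROUPS.items() for seed in seeds
    }
    affinity = {
        g: (targets, float(multiplier)) for g, targets in PAPER_AFFINITY_TARGETS.items()
    }
    truth = SyntheticTruth(group_of_seed=group_of_seed, affinity=affinity, rng_seed=rng_seed)
    if not split_hemispheres:
        truth.validate(atlas)
    return atlas, truth


def make_generic_atlas(n_seeds: int, n_targets: int) -> AtlasTable:
    """Minimal merged atlas with ``n_seeds`` seed parcels S1.. and
    ``n_targets`` target parcels T1.. (used for calibration experiments)."""
    rows = [(f"S{i + 1}", f"S{i + 1}", "merged", "insular", True, "") for i in range(n_seeds)]
    rows += [(f"T{j + 1}", f"T{j + 1}", "merged", "other", False, "") for j in range(n_targets)]
    return AtlasTable(pd.DataFrame(
        rows,
        columns=["parcel_id", "parcel_name", "hemisphere", "macro_region",
                 "is_insular_seed", "granularity"],
    ))


def make_null_truth(atlas: AtlasTable, rng_seed: int = 0, **kwargs) -> SyntheticTruth:
    """Exchangeable-null truth on any atlas: one group, multiplier 1, so every
    seed's marginal FBC distribution is identical per target."""
    group_of_seed = {s: "null" for s in atlas.seed_ids}
    truth = SyntheticTruth(
        group_of_seed=group_of_seed,
        affinity={"null": ((), 1.0)},
        rng_seed=rng_seed,
        **kwargs,
    )
    truth.validate(atlas)
    return truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _location_matrix(atlas: AtlasTable, truth: SyntheticTruth) -> np.ndarray:
    ids = atlas.parcel_ids
    pos = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    if isinstance(truth.baseline_loc, Mapping):
        default = float(np.mean(list(truth.baseline_loc.values())))
        per = np.array([float(truth.baseline_loc.get(pid, default)) for pid in ids])
        loc = (per[:, None] + per[None, :]) / 2.0
    else:
        loc = np.full((n, n), float(truth.baseline_loc), dtype=float)
    for seed, group in truth.group_of_seed.items():
        if seed not in pos:
            continue
        targets, mult = truth.affinity[group]
        si = pos[seed]
        bump = np.log(mult)
        for t in targets:
            ti = pos[t]
            loc[si, ti] += bump
            loc[ti, si] += bump
    return loc


def simulate_cohort(
    atlas: AtlasTable,
    truth: SyntheticTruth,
    n_subjects: int,
    rng_seed: int | None = None,
    cohort_id: str = "synthetic",
) -> list[SubjectConnectome]:
    """Draw ``n_subjects`` symmetric FBC matrices from the planted model.

    Fully reproducible: the same seed yields bit-identical cohorts. Outlier
    subjects (``round(outlier_fraction * n)`` of them, chosen by the RNG) have
    their whole matrix multiplied by ``outlier_multiplier``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    truth.validate(atlas)
    seed = truth.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0x5EED]))
    ids = atlas.parcel_ids
    n = len(ids)
    loc = _location_matrix(atlas, truth)
    iu = np.triu_indices(n, k=1)
    loc_u = loc[iu]
    n_out = int(round(truth.outlier_fraction * n_subjects))
    outliers = set(rng.choice(n_subjects, size=n_out, replace=False).tolist()) if n_out else set()
    cohort = []
    for s in range(n_subjects):
        z = rng.standard_normal(loc_u.size)
        vals = np.exp(loc_u + truth.baseline_scale * z) * truth.cohort_scale
        if s in outliers:
            vals = vals * truth.outlier_multiplier
        m = np.zeros((n, n))
        m[iu] = vals
        m = m + m.T
        cohort.append(
            SubjectConnectome(f"{cohort_id}-{s:04d}", pd.DataFrame(m, index=ids, columns=ids))
        )
    return cohort


def simulate_second_cohort(
    atlas: AtlasTable,
    truth: SyntheticTruth,
    scale: float,
    n_subjects: int,
    rng_seed: int | None = None,
    cohort_id: str = "replication",
) -> list[SubjectConnectome]:
    """Independent cohort from the same planted structure with all FBC values
    globally multiplied by ``scale`` (emulating a replication data set with an
    elevated FBC scale)."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    seed = truth.rng_seed + 1 if rng_seed is None else rng_seed
    scaled = replace(truth, cohort_scale=truth.cohort_scale * scale)
    return simulate_cohort(atlas, scaled, n_subjects, rng_seed=seed, cohort_id=cohort_id)
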