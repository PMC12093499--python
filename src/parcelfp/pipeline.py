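"""End-to-end pipeline orchestration from a single config.

One ``RunConfig`` (YAML or dict) drives: cohort simulation or ingestion →
fingerprint → bootstrap specificity → feature selection and clustering →
gated contrasts → integrative connectivity → (with a second cohort)
replication concordance. Every stage writes a TSV; a JSON manifest records
the config hash and every derived RNG seed, and re-running with the same
master seed reproduces bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import cluster as clustering
from . import contrasts as contrasts_mod
from . import specificity as spec_mod
from .atlas import AtlasTable, load_atlas, write_atlas
from .core import (
    Fingerprint,
    SubjectConnectome,
    assemble_cohort,
    combine_hemispheres,
    fingerprint_matrix,
    load_subject_matrix,
    whole_brain_fingerprint,
    write_subject_matrix,
)
from .integration import hub_overlap_map, integrative_score, limited_strength_mask
from .synthetic import SyntheticTruth, make_paper_atlas, simulate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"

# fixed per-stage seed offsets spawned from the master seed
_STAGE_OFFSETS = {"simulate": 11, "specificity": 23, "cluster": 37, "contrast": 41,
                  "integrate": 53, "replicate": 67}


@dataclass
class RunConfig:
    """Validated pipeline configuration (one structured key-value file)."""

    output_dir: str
    rng_seed: int = 0
    trim_fraction: float = 0.1
    n_iter: int = 10_000
    percentile: float = 99.0
    alpha: float = 0.01
    d_min: float = 0.8
    k_range: tuple[int, int] = (2, 8)
    top_fraction: float = 0.5
    atlas_path: str | None = None  # None -> built-in study-structured atlas
    run_integration: bool = True
    cohorts: list[dict] = field(default_factory=lambda: [
        {"id": "discovery", "synthetic": {"n_subjects": 100, "multiplier": 3.0, "scale": 1.0}}
    ])

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        if not 50 < self.percentile < 100:
            raise ValueError("percentile must be in (50, 100)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError("k_range must be (lo, hi) with 2 <= lo <= hi")
        if not 1 <= len(self.cohorts) <= 2:
            raise ValueError("pipeline supports 1 or 2 cohort blocks")
        if self.atlas_path is not None and not os.path.exists(self.atlas_path):
            raise FileNotFoundError(self.atlas_path)
        for block in self.cohorts:
            if "manifest" in block and not os.path.exists(block["manifest"]):
                raise FileNotFoundError(f"ingest stage: manifest not found: {block['manifest']}")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return RunConfig(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        d["k_range"] = list(self.k_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(
    out_dir: str,
    connectomes: Sequence[SubjectConnectome],
    atlas: AtlasTable,
    truth: SyntheticTruth | None = None,
) -> str:
    """Write per-subject matrix TSVs plus a ``manifest.tsv`` (subject_id →
    path), the atlas, and the generating truth if given. Returns the manifest
    path."""
    os.makedirs(out_dir, exist_ok=True)
    write_atlas(atlas, os.path.join(out_dir, "atlas.tsv"))
    rows = []
    for conn in connectomes:
        fname = f"{conn.subject_id}.tsv"
        write_subject_matrix(conn, os.path.join(out_dir, fname))
        rows.append({"subject_id": conn.subject_id, "path": fname})
    manifest = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if truth is not None:
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            fh.write(truth.to_json())
    return manifest


def load_manifest(manifest_path: str, atlas: AtlasTable) -> list[SubjectConnectome]:
    """Read a cohort manifest TSV (columns subject_id, path; paths relative to
    the manifest's directory) into subject connectomes."""
    base = os.path.dirname(os.path.abspath(manifest_path))
    t = pd.read_csv(manifest_path, sep="\t", dtype=str)
    if not {"subject_id", "path"} <= set(t.columns):
        raise ValueError("manifest needs columns subject_id, path")
    out = []
    for _, row in t.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        out.append(load_subject_matrix(p, atlas, subject_id=row["subject_id"]))
    return out


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def polar_fingerprint_table(cl_fingerprint: Fingerprint) -> pd.DataFrame:
    """Long-format cluster x target table of fingerprint values, the data
    behind a polar fingerprint plot."""
    df = cl_fingerprint.values.reset_index(names="cluster")
    long = df.melt(id_vars="cluster", var_name="target", value_name="value")
    # preserve cluster-major, canonical-target order
    long["_c"] = pd.Categorical(long["cluster"], categories=cl_fingerprint.row_ids)
    long["_t"] = pd.Categorical(long["target"], categories=cl_fingerprint.target_ids)
    long = long.sort_values(["_c", "_t"]).drop(columns=["_c", "_t"]).reset_index(drop=True)
    return long


def contrast_table(results: Sequence[contrasts_mod.ContrastResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for _, c in r.table.iterrows():
            rows.append({
                "target": r.target, "top_cluster": r.top_cluster,
                "competitor": c["competitor"], "p": c["p"], "d": c["d"],
                "d_ci_low": c["d_ci_low"], "d_ci_high": c["d_ci_high"],
                "pass": r.passed,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stage_seed(master: int, stage: str, extra: int = 0) -> int:
    return (int(master) * 1_000_003 + _STAGE_OFFSETS[stage] * 7919 + extra) % (2**31)


def _get_cohort(block: Mapping, atlas: AtlasTable, truth_template: SyntheticTruth | None,
                master_seed: int, index: int):
    """Simulate or ingest one cohort block; returns (connectomes, atlas)."""
    cid = block.get("id", f"cohort{index + 1}")
    if "manifest" in block:
        try:
            conns = load_manifest(block["manifest"], atlas)
        except Exception as exc:
            raise RuntimeError(f"ingest stage failed for cohort {cid!r}: {exc}") from exc
        if any(h != "merged" for h in atlas.table["hemisphere"]):
            conns = [combine_hemispheres(c, atlas, mode="mean") for c in conns]
            atlas = atlas.merge_hemispheres()
        return cid, conns, atlas
    syn = block.get("synthetic", {})
    if truth_template is None:
        raise RuntimeError("synthetic cohort block requires the built-in atlas")
    truth = truth_template.with_multiplier(float(syn.get("multiplier", 3.0)))
    scale = float(syn.get("scale", 1.0))
    if scale != 1.0:
        from dataclasses import replace
        truth = replace(truth, cohort_scale=truth.cohort_scale * scale)
    n = int(syn.get("n_subjects", 100))
    conns = simulate_cohort(atlas, truth, n,
                            rng_seed=_stage_seed(master_seed, "simulate", index),
                            cohort_id=cid)
    return cid, conns, atlas


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write all stage TSVs plus ``run_manifest.json``
    under ``config.output_dir``; returns the manifest dict. Idempotent under a
    fixed master seed."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    master = config.rng_seed
    tf = config.trim_fraction
    outputs: dict[str, str] = {}
    seeds: dict[str, int] = {}

    if config.atlas_path is not None:
        atlas = load_atlas(config.atlas_path)
        truth_template = None
    else:
        atlas, truth_template = make_paper_atlas()

    cohort_results = []
    for i, block in enumerate(config.cohorts):
        cid, conns, catlas = _get_cohort(block, atlas, truth_template, master, i)
        seeds[f"simulate.{cid}"] = _stage_seed(master, "simulate", i)
        cohort = assemble_cohort(conns, catlas, cohort_id=cid)
        fp = fingerprint_matrix(cohort, tf)
        cohort_results.append((cid, conns, catlas, cohort, fp))
        _write(fp.values, os.path.join(out, f"fingerprint_{cid}.tsv"), outputs, index=True)

    # --- specificity (per cohort) ------------------------------------------
    spec_maps = {}
    for i, (cid, _, _, cohort, fp) in enumerate(cohort_results):
        sseed = _stage_seed(master, "specificity", i)
        seeds[f"specificity.{cid}"] = sseed
        nulls = spec_mod.all_target_nulls(cohort, config.n_iter, tf, sseed, config.percentile)
        gnull = spec_mod.global_null(cohort, config.n_iter, tf, sseed, config.percentile)
        smap = spec_mod.classify_specificity(fp, nulls, gnull)
        spec_maps[cid] = (smap, nulls, gnull)
        _write(smap.to_long(), os.path.join(out, f"specificity_{cid}.tsv"), outputs)

    # --- clustering on the primary cohort ----------------------------------
    cid0, conns0, atlas0, cohort0, fp0 = cohort_results[0]
    smap0 = spec_maps[cid0][0]
    features = clustering.select_features(smap0)
    pd.Series(features, name="target").to_frame().pipe(
        _write, os.path.join(out, "features.tsv"), outputs)
    dist = clustering.manhattan_matrix(fp0, features)
    cseed = _stage_seed(master, "cluster", 0)
    seeds["cluster"] = cseed
    km = clustering.kmeans_elbow(fp0, features, range(config.k_range[0], config.k_range[1] + 1),
                                 rng_seed=cseed)
    hier = clustering.hierarchical_cluster(dist, k=km.k)
    mds = clustering.mds_embed(dist)
    labels_df = pd.DataFrame({
        "seed": list(km.entity_ids),
        "kmeans_label": [km.labels[e] for e in km.entity_ids],
        "hierarchical_label": [hier.labels[e] for e in hier.entity_ids],
    })
    _write(labels_df, os.path.join(out, "cluster_labels.tsv"), outputs)
    _write(pd.DataFrame(hier.linkage_tree,
                        columns=["node_a", "node_b", "height", "size"]),
           os.path.join(out, "linkage.tsv"), outputs)
    _write(pd.DataFrame({"k": list(km.inertia_curve), "inertia": list(km.inertia_curve.values())}),
           os.path.join(out, "inertia_curve.tsv"), outputs)
    _write(mds.reset_index(names="seed"), os.path.join(out, "mds_coords.tsv"), outputs)
    summary = {
        "optimal_k": km.k,
        "cophenetic_correlation": hier.cophenetic_correlation,
        "n_features": len(features),
    }

    # --- cluster fingerprints + polar table + contrasts ---------------------
    labels = {e: km.labels[e] for e in km.entity_ids}
    clfp = clustering.cluster_fingerprint(cohort0, labels, tf)
    _write(polar_fingerprint_table(clfp), os.path.join(out, "polar_fingerprint.tsv"), outputs)
    groups = {n: [t for t in members if t in set(cohort0.target_ids)]
              for n, members in contrasts_mod.TARGET_GROUPS.items()}
    groups = {n: m for n, m in groups.items() if m}
    tseed = _stage_seed(master, "contrast", 0)
    seeds["contrast"] = tseed
    results = contrasts_mod.contrast_all_targets(
        cohort0, labels, groups, config.alpha, config.d_min, rng_seed=tseed)
    _write(contrast_table(results), os.path.join(out, "contrasts.tsv"), outputs)

    # --- integration (primary cohort, whole brain) --------------------------
    if config.run_integration:
        iseed = _stage_seed(master, "integrate", 0)
        seeds["integrate"] = iseed
        wfp = whole_brain_fingerprint(conns0, tf)
        whole = assemble_cohort(conns0, atlas0, seeds=atlas0.parcel_ids,
                                targets=atlas0.parcel_ids, cohort_id=f"{cid0}-whole")
        wnulls = spec_mod.all_target_nulls(whole, config.n_iter, tf, iseed, config.percentile)
        thr = {t: nd.threshold for t, nd in wnulls.items()}
        mask = limited_strength_mask(wfp, thr, config.top_fraction)
        imap = integrative_score(mask, config.top_fraction)
        idf = pd.DataFrame({"parcel": list(imap.fraction.index),
                            "integrative_fraction": imap.fraction.to_numpy(),
                            "bin": imap.bins.to_numpy()})
        _write(idf, os.path.join(out, "integrative_fraction.tsv"), outputs)
        insular = [s for s in atlas0.seed_ids]
        top2 = imap.fraction.loc[insular].sort_values(ascending=False).index[:2].tolist()
        if len(top2) == 2:
            overlap = hub_overlap_map(mask, top2[0], top2[1])
            odf = pd.DataFrame({"parcel": overlap.index, "category": overlap.to_numpy()})
            _write(odf, os.path.join(out, "hub_overlap.tsv"), outputs)
            summary["hub_rois"] = top2

    # --- replication ---------------------------------------------------------
    if len(cohort_results) == 2:
        cid1, _, _, cohort1, _ = cohort_results[1]
        rseed = _stage_seed(master, "replicate", 0)
        seeds["replicate"] = rseed
        concord = _cluster_concordance(cohort0, cohort1, labels, config, tf, rseed)
        cdf = concord.categories.reset_index(names="cluster").melt(
            id_vars="cluster", var_name="target", value_name="category")
        _write(cdf, os.path.join(out, "concordance.tsv"), outputs)
        summary["discordant_fraction"] = concord.discordant_fraction

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "derived_seeds": seeds,
        "outputs": outputs,
        "summary": summary,
    }
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _cluster_concordance(cohort_a, cohort_b, labels, config: RunConfig, tf: float,
                         rseed: int):
    """Cluster-level specificity in each cohort (each against its own nulls),
    then the concordance map."""
    maps = []
    for k, cohort in enumerate((cohort_a, cohort_b)):
        cl = clustering.cluster_cohort(cohort, labels)
        fp = fingerprint_matrix(cl, tf)
        nulls = spec_mod.all_target_nulls(cl, config.n_iter, tf, rseed + k, config.percentile)
        gnull = spec_mod.global_null(cl, config.n_iter, tf, rseed + k, config.percentile)
        maps.append(spec_mod.classify_specificity(fp, nulls, gnull))
    return contrasts_mod.replication_concordance(maps[0], maps[1])


def _write(df: pd.DataFrame, path: str, outputs: dict, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    outputs[os.path.basename(path)] = path
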