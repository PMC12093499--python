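"""Effect-size-gated cluster contrasts and cross-cohort replication.

For a target region, the cluster with the highest per-subject FBC must beat
every other cluster at p < 0.01 (one-sided Welch t) AND with a Cohen's d
bootstrap CI whose lower bound exceeds 0.8 — a gate against the vanishing
p values of large cohorts. Replication compares the bootstrap-threshold
decisions of two cohorts drawn from the same structure at different FBC
scales.
"""

import parcelfp as p

atlas, truth = p.make_paper_atlas()
labels = truth.true_labels()
cohort = p.assemble_cohort(p.simulate_cohort(atlas, truth, 200, rng_seed=3), atlas)

vals = p.subject_cluster_fbc(cohort, labels, list(p.TARGET_GROUPS["Orbitofrontal"]))
res = p.contrast_test(vals, "Orbitofrontal", alpha=0.01, d_min=0.8, rng_seed=3)
print(f"Orbitofrontal: top cluster = {res.top_cluster}, pass = {res.passed}")
print(res.table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("-> the ventral anterior cluster outperforms every competitor with a"
      " large, CI-supported effect.\n")

# replication against a second cohort with globally doubled FBC
maps = []
for scale, seed in ((1.0, 30), (2.0, 31)):
    conns = p.simulate_second_cohort(atlas, truth, scale, 200, rng_seed=seed)
    cl = p.cluster_cohort(p.assemble_cohort(conns, atlas), labels)
    fp = p.fingerprint_matrix(cl)
    maps.append(p.classify_specificity(
        fp, p.all_target_nulls(cl, 2000, rng_seed=seed),
        p.global_null(cl, 2000, rng_seed=seed)))
concord = p.replication_concordance(maps[0], maps[1])
print("replication concordance (cluster x target decisions):")
for k, v in concord.counts().items():
    print(f"  {k:18s} {v:4d}")
print(f"discordant fraction: {concord.discordant_fraction:.3f}")
print("-> decisions replicate because each cohort is tested against its own"
      " bootstrap thresholds; the global FBC scale difference cancels out.")
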