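"""Where does the classifier look? Grad-CAM and network occlusion.

Plants a rest-only sex effect on the salience network's 45 inner edges,
trains a small ensemble, and asks both interpretability procedures to find
it: guided Grad-CAM should give those edges elevated saliency (positive
Cohen's d against all other edges), and occluding them out of the input
should cost rest-stratum accuracy while task accuracy stays at chance.

CAM attribution needs members that have genuinely learned the 45-edge
signal (weak members contribute louder noise saliency than strong members
contribute signal), hence the larger cohort here. Roughly ten minutes on
one CPU (6 CAM members + 2 x 8 occlusion members).
"""

import connectoscramble as cs

networks = cs.load_networks()
spec = cs.CohortSpec(n_subjects=1200, seed=13).with_effects(
    cs.EffectEntry(nodes=networks["SAL"].nodes, condition="rest", d=1.5)
)
table = cs.generate_phenotypes(spec)
stacks = cs.generate_connectomes(table, spec)

# --- Grad-CAM ------------------------------------------------------------
config = cs.EnsembleConfig(n_members=6, member=cs.MemberConfig(epochs=30),
                           seed=2)
result = cs.run_ensemble(stacks, table, config, compute_curve=False)
cams = cs.aggregate_cams(result.members, stacks,
                         table["subject_id"].to_numpy())
report = cs.network_effect_sizes(cams, networks, table)
print("CAM effect sizes (Cohen's d, edge set vs all other edges):")
print(report.query("edge_set == 'inner'")
      .pivot(index="network", columns="stratum", values="d").round(3))

# --- occlusion -----------------------------------------------------------
design = cs.OcclusionDesign(network_name="SAL", nodes=networks["SAL"].nodes,
                            edge_mode="inner", n_members=8)
occ_cfg = cs.EnsembleConfig(n_members=1, member=cs.MemberConfig(epochs=12),
                            seed=4)
occ = cs.run_occlusion(stacks, table, [design], occ_cfg)
cols = ["stratum", "auroc_include_mean", "auroc_exclude_mean", "p_holm"]
print("\nocclusion, salience inner edges (8 members per arm):")
print(occ[cols].round(4).to_string(index=False))
print("\nonly the rest stratum pays for losing the salience edges -- the "
      "planted effect is condition-specific, and occlusion localizes it; "
      "the CAM table shows the same edges are what the models attend to.")
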