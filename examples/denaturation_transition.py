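"""The headline experiment: one distal cross-link restrains a whole fold.

Denatures the Y fixture under random SSE perturbation while predicted
contacts are imposed one by one in ranked order, and prints the mean-RMSD
profile.  The sharp drop at k = 1 is the imposition of the loop-loop
cross-link; the local-only control shows no such transition.

Runs at reduced scale (5 replicates, 500 cycles) to finish in about a
minute; the full protocol uses 10 replicates of 1000 cycles.
"""

from tracefold import (
    SimConfig,
    TopologySpec,
    build_topology,
    classify,
    control_profiles,
    denaturation_profile,
    synth_predictions,
)

built = build_topology(
    TopologySpec("Y", (4, 6, 6), (4, 4), cross_links=((0, 1),))
)
preds, labels = synth_predictions(built, n_true_nonlocal=1, n_false=0, n_local=9)
preds = classify(preds, built.chain, built.ss, built.ss.nested)

cfg = SimConfig(cycles=500, perturb_translation=0.08, replicates=5, seed=1)
profile = denaturation_profile(built.chain, built.ss, preds, cfg)
observed, _ = control_profiles(
    built.chain, built.ss, built.ss.nested, built.ss.nested, cfg, max_k=10
)

print("k   predicted  control   (mean RMSD over replicates, A)")
for k, (p, c) in enumerate(zip(profile.points, observed.points)):
    tag = f"  <- {profile.annotations[k - 1]}" if k else ""
    print(f"{k:2d}  {p:8.3f}  {c:8.3f}{tag}")
drops = profile.drops
print(f"\nlargest single-step drop: {drops.max():.3f} A at k = {drops.argmax() + 1}")
print("the k = 1 restraint is the distal loop-loop cross-link; base-pair "
      "restraints at k >= 2 change almost nothing because the stems are "
      "already held rigid, and the local-only control stays flat")
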