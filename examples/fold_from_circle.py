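"""Restrained folding from an extended circular start.

Folds the Y fixture from the default circular conformation twice: once with
only the observed (local) base pairs as 17-angstrom restraints, and once with
the distal cross-link added.  The non-local restraint steers the arms into
their native arrangement, so the predicted-set models land closer to the
native structure — the folding-direction counterpart of the denaturation
transition.
"""

from tracefold import SimConfig, TopologySpec, build_topology, fold

built = build_topology(
    TopologySpec("Y", (4, 6, 6), (4, 4), cross_links=((0, 1),))
)
cfg = SimConfig(cycles=1000, replicates=10, seed=1)
cross = [tuple(p) for p in built.cross_links]

observed_only = fold(built.chain, built.ss, [], cfg, n_runs=10,
                     restraint_source="observed")
with_link = fold(built.chain, built.ss, cross, cfg, n_runs=10,
                 restraint_source="predicted")

print(f"models per condition: {observed_only.n_models}")
print(f"Ro (observed pairs only)      best-10 mean RMSD: "
      f"{observed_only.best10_mean_rmsd:6.2f} A")
print(f"Rp (plus distal cross-link)   best-10 mean RMSD: "
      f"{with_link.best10_mean_rmsd:6.2f} A")
print("Rp < Ro: the single non-local restraint carries most of the fold "
      "information that the local pairs cannot provide")
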