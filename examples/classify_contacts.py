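"""Rank, truncate and classify a scored contact table.

Loads the fixture written by build_fixture.py (building it on the fly if
needed), applies the N = 5 + L/4 selection rule, and labels every kept
contact against the known structure.
"""

from pathlib import Path

from tracefold import (
    TopologySpec,
    build_topology,
    classify,
    cutoff_count,
    error_rate_cutoff,
    parse_dotbracket,
    read_contact_table,
    read_phosphate_trace,
    select_top,
    SecondaryStructure,
    synth_predictions,
    write_simrna_restraints,
)

out = Path(__file__).resolve().parent / "output"
if (out / "y.pdb").exists():
    chain = read_phosphate_trace((out / "y.pdb").read_text())
    ss = SecondaryStructure.from_pairs(
        parse_dotbracket((out / "y.ss").read_text()), len(chain)
    )
    preds = read_contact_table((out / "y.contacts.tsv").read_text())
else:
    built = build_topology(
        TopologySpec("Y", (4, 6, 6), (4, 4), cross_links=((0, 1),))
    )
    chain, ss = built.chain, built.ss
    preds, _ = synth_predictions(built, n_true_nonlocal=1, n_false=2, seed=1)

L = len(chain)
print(f"molecule length L = {L}; selection rule keeps N = 5 + L/4 = "
      f"{cutoff_count(L)} contacts")
kept = select_top(classify(preds, chain, ss, ss.nested), L).entries
for p in kept:
    print(f"  rank {p.rank:2d}  {p.i + 1:3d}-{p.j + 1:<3d} score {p.score:5.2f}  {p.category}")
print("categories: shared_local = also in the thermodynamic pair set, "
      "extra_local = further observed nested pair,")
print("non_local = true distal contact (native distance <= 21 A), "
      "false = over 21 A in the native structure")
k = error_rate_cutoff(kept, 0.05)
print(f"a 5% error-rate cutoff would keep the top {k} of {len(kept)}")
print("\nSimRNA restraints for the two strongest contacts:")
print(write_simrna_restraints([(p.i + 1, p.j + 1) for p in kept[:2]]), end="")
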