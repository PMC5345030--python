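# tracefold

Coarse-grained phosphate-trace RNA simulation for evaluating
coevolution-derived distance restraints.

## The problem

Correlated-mutation analysis of an RNA sequence alignment yields a ranked,
scored list of candidate residue contacts.  Most of the reliable ones are
secondary-structure base pairs that thermodynamic folding already predicts;
the scientifically valuable minority are *non-local* contacts — links between
stem-loops, pseudoknot pairs — that pin down the tertiary fold.  `tracefold`
asks, structure by structure and restraint by restraint, how much
conformational restriction each predicted contact actually buys.

Rather than folding from scratch, the main protocol inverts the problem: the
known structure is "denatured" under controlled random perturbation of its
secondary-structure elements while predicted contacts are imposed one at a
time, strongest first, as distance restraints.  A contact that genuinely
restrains the fold shows up as a sharp drop in the mean deviation from the
native structure at the step where it is introduced.

## The model

* An RNA of length $L$ is a **phosphate trace**: one point per nucleotide.
* Ladders of $\ge 3$ consecutive base pairs are **secondary-structure
  elements (SSEs)**, treated as rigid tubes.  Each simulation cycle displaces
  every SSE by a random translation (up to 0.08 Å) and rotation (up to
  0.08 rad) about its centroid.
* Geometric refinement terms then each move atom pairs by at most a fixed
  0.5 Å step per cycle:
  * SSE internal geometry → ideal duplex template;
  * consecutive P–P virtual bonds → 6 Å;
  * local distances within a 10-residue window → their starting values,
    applied only while the current distance is under 18 Å (so large
    conformational changes remain acceptable);
  * restrained pairs with separation above the 17 Å target are contracted
    (one-sided; pairs at or below target are never touched);
  * non-bonded pairs closer than 10 Å are repelled.
* Deviation is measured as superposition RMSD, distance-matrix dRMSD
  ($\sqrt{\mathrm{mean}_{i<j}(d^a_{ij}-d^b_{ij})^2}$), and dRMSD$_{\max}$
  (dRMSD of the per-pair maximum-distance matrix of an ensemble).
* A ranked contact list is truncated to $N = 5 + L/4$ contacts and each kept
  contact is classified as `shared_local`, `extra_local`, `non_local`
  (native P–P distance $\le 21$ Å) or `false` (over 21 Å).

The package also builds ideal-geometry toy structures (helix, stem-loop, Y,
cruciform) with planted true and false contacts, so every protocol is
testable without any external downloads, and writes SimRNA-dialect
restraint files (`WELL`/`SLOPE` lines) for cross-checking with a full-atom
simulator.

## A worked example

```sh
python examples/denaturation_transition.py
```

builds the two-armed Y fixture (48 nt, 16 bp, a loop–loop cross-link planted
at 16.78 Å), then denatures it under ten ranked predicted contacts
(reduced scale: 5 replicates × 500 cycles):

```
k   predicted  control   (mean RMSD over replicates, A)
 0     2.942     2.942
 1     2.630     2.945  <- non_local
 2     2.634     2.944  <- shared_local
 ...
10     2.669     2.996  <- shared_local

largest single-step drop: 0.312 A at k = 1
```

The drop at k = 1 is the imposition of the distal loop–loop cross-link — the
only restraint carrying tertiary information.  Base-pair restraints (k ≥ 2)
change nothing because the stems are already rigid, and the local-only
control profile stays flat.  `examples/fold_from_circle.py` shows the same
effect in the folding direction: from a circular start, the best-10 mean
RMSD is 12.87 Å with the cross-link versus 16.57 Å with local pairs only.

The other examples cover fixture construction (`build_fixture.py`) and
contact classification / selection cutoffs (`classify_contacts.py`).  A thin
CLI wraps the same entry points: `tracefold synth | restraints | simulate |
metrics | denature | fold` (see `--help`).

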