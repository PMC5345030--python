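# Methods

## Model and procedure

`tracefold` simulates RNA at one point per nucleotide — the phosphate — with
secondary structure imposed as rigidity rather than energetics.  Ladders of
three or more antidiagonally consecutive base pairs ((i, j), (i+1, j−1), …)
are secondary-structure elements (SSEs); any bulge terminates a ladder.  Each
SSE carries an ideal internal distance template and moves as a rigid body.

A simulation cycle applies, in order:

1. **Random SSE perturbation** — per SSE, a translation of magnitude uniform
   in [0, level] Å along a uniform random direction, and a rotation of angle
   uniform in [0, level] rad about a uniform random axis through the SSE
   centroid.  Loop and linker residues receive no direct kick; they move only
   through the refinement terms.  The translation and rotation levels are
   swept together (0.02–0.10); 0.08 is the working default.
2. **SSE ideal geometry** — intra-element pairwise distances are refined
   toward the template.
3. **Bond regularization** — consecutive P–P distances toward 6.0 Å.
4. **Local window** — distances between residues 2–9 apart in sequence are
   refined toward their values in the *starting* structure, but only while
   the current distance is below the 18 Å gate.  This keeps loops locally
   native-like yet lets segments that have escaped keep moving, so large
   conformational changes remain acceptable.
5. **Pair restraints** — restrained pairs with separation above the 17 Å
   target are contracted; pairs at or below target are never touched
   (one-sided).  Local and non-local restraints are treated identically.
6. **Repulsion** — non-bonded pairs (sequence separation ≥ 2, not within one
   SSE, not restrained) closer than 10 Å are pushed apart.

Every term moves a pair's two atoms symmetrically along their connecting
axis, changing the pair distance by at most the step size (0.5 Å per cycle;
chosen so a thousand cycles can close several hundred ångströms of
violation).  Per-atom contributions from the one-sided push terms
(restraints, repulsion) are summed and the net displacement capped at the
step.  For the distance-matching terms (bonds, local window, SSE template)
the per-atom corrections are instead *averaged* over the atom's deviating
pairs — a Jacobi-style distance-geometry iteration.  Plain summation over
the O(k²) overlapping pairs of these terms has loop gain above one: it
amplifies numerical noise into a sustained ±step oscillation around the
native state (we measured ≈2.5 Å RMSD of pure oscillation at zero
perturbation before making this choice).  With averaging, a consistent
starting structure is an exact fixed point of the whole cycle.  Single-pair
behaviour — the probes used for the acceptance constants — is identical
under both conventions.

Ordering puts restraints after the local terms, so imposed cross-links win
conflicts, and repulsion last.  Conflicting shifts within one term are
resolved as above; terms see each other's output sequentially.

## Deviation measures

* `superpose_rmsd` — least-squares rigid superposition (Kabsch, proper
  rotations only; a mirror image scores badly, as it should for a chiral
  backbone).
* `drmsd` — root-mean-square over all n(n−1)/2 pairwise-distance deviations.
  The root-mean-square normalization (rather than a bare sum of squares)
  makes values comparable across molecule lengths.
* `drmsd_max` — dRMSD between the entrywise maximum distance matrix of an
  ensemble and the native matrix, capturing the full reach of the ensemble
  rather than its mean.  The alternative convention (maximum of per-model
  dRMSDs) is a one-liner on the same API and is not the default.
* `per_residue_rmsd` — per-position RMS displacement after each model's
  global superposition; identifies which segments a restraint set pins.

## Protocols

The **denaturation profile** runs the simulator on the native structure for
each prefix of the ranked restraint list (k = 0 … N restraints, prefix k ⊂
prefix k+1) and records mean superposition RMSD over replicates (default 10
replicates × 1000 cycles).  The k = 0 runs carry no test-set restraints but
keep all local terms — that is how unrestrained runs still hold loops
loosely.  Replicate random streams are derived from the master seed and the
replicate index only, so all prefix sizes see identical perturbation
sequences.  This paired design means the k → k+1 difference isolates the
effect of the (k+1)-th restraint; with independent streams the seed noise
between prefix sizes (≈0.3 Å at this problem size) would drown the signal of
a single restraint.  **Control profiles** run the same procedure on the
observed nested pairs and on the thermodynamically predicted pair set —
local-only sets that should show no restriction drop.

**Folding** starts from L points equally spaced on a circle of circumference
6L (consecutive chords just under the bond ideal), imposes the base pairs of
the secondary structure plus any extra contacts as 17 Å restraints, and
scores the ten models closest to the native.  The native enters scoring
only.  Because the start is planar and the dynamics are
reflection-equivariant, folded models may land in the mirror topology; both
restraint conditions are affected equally, so the comparison between them
stands.

**Restraint selection**: a ranked contact list is truncated to
N = 5 + ⌊L/4⌋ (floor; any consistent rounding differs by at most one
contact).  Classification precedence is: membership in the thermodynamic
pair set, then in the observed nested set, then native phosphate distance —
at most 21 Å is `non_local`, strictly over 21 Å is `false`.  Distances use
phosphate atoms throughout, the only atoms the representation has.  An
error-rate cutoff (largest prefix whose false fraction stays within a
budget) is provided alongside the linear rule.

## The synthetic fixtures

The fixture builder emulates the three inputs — structure, secondary
structure, scored contact table — with ideal geometry, so every protocol is
testable without downloads.

Stems use a regular duplex solved in closed form from the engine's own
ideals: intra-strand bond exactly 6.0 Å and paired cross-strand distance
exactly 17.0 Å, with an 11 bp/turn twist and a 3.2 Å rise.  The rise is
steeper than A-form RNA (2.8 Å) — it is the value at which hairpin-loop
take-offs clear the stem body at the 10 Å repulsion threshold, keeping built
structures exact fixed points of the engine.  Hairpin loops are circular
arcs at bond spacing; inter-segment linkers are cubic Hermite curves whose
end tangents continue the neighbouring backbone directions, resampled at
equal arc length (circular arcs cannot be tangent-matched at both ends, and
tangent mismatch at junctions is exactly what creates sub-10 Å
second-neighbour contacts).

Multi-element topologies (Y, cruciform) have genuinely open placement
freedom: each arm's spin about its own axis, the hairpin-loop tilt, and the
junction radius.  The builder grid-searches these deterministically,
relaxes marginal drafts with the engine's own bond and repulsion terms while
freezing stem atoms, and keeps the arrangement that satisfies the
construction contract: non-bonded, non-intra-SSE clearance ≥ 10 Å, bonds
within 0.2 Å of ideal, and — when a cross-link is requested — the closest
loop–loop contact inside the 10–17 Å band and as close to 17 Å as
available.  Planting the designed contact just inside the restraint target
reflects the geometry of the real use case: a covarying loop–loop contact
sits near the restraint distance in the native structure, so the one-sided
restraint engages exactly when denaturation drives the loops apart.

`synth_predictions` assembles the scored table: the structure's base pairs,
the planted cross-links, and optional false pairs (random pairs with native
distance over 21 Å, sequence separation ≥ 4), with group score levels
separated by a configurable gap.  By default the non-local contacts rank
first (the strong-covariation case); ground-truth labels ship separately so
tests can verify the classifier round-trips them.

What the fixtures deliberately do not emulate: sequence content, A-form
atomic geometry, bulged or interrupted stems (each arm is a single SSE),
alignment noise in the scores, and any energetic preference beyond the
engine's geometric rules.  Passing tests therefore demonstrate the
mechanics of restraint evaluation — not predictive performance on real
RNA, which depends on alignment depth and contact-prediction quality.

## Scale of the shipped experiments

The acceptance-level experiments run the full protocol (10 replicates ×
1000 cycles) on the Y fixture: a 4 bp trunk and two 6 bp arms with 4-residue
hairpin loops (48 nt) — the smallest topology with the branching geometry
the denaturation mechanism needs, and comfortably desk-scale.  At these
conditions the cross-link transition at k = 1 is 0.3–0.5 Å against a
±0.02 Å paired-design noise floor.  Engine-constant probes use two- and
three-residue chains and converge in well under a second.

## Numerical choices and degenerate inputs

* Coincident points (zero-length pair axis) displace along a fixed fallback
  axis, keeping behaviour deterministic.
* The maximum-nested-subset decomposition is an interval dynamic programme;
  equal-cardinality ties prefer pairs with smaller i, so the decomposition
  is reproducible.  (Whether an external annotation would call the same
  subset "nested" is a convention question; maximum cardinality is computed
  here and stated as such.)
* Bracket layers for crossing pairs are assigned greedily to the first
  non-conflicting layer of `()[]{}<>`; more than four mutually crossing
  layers is an error.
* Contact tables are 1-based on disk and deduplicated keeping the maximum
  score; score ties break by ascending (i, j).  All internal indices are
  0-based; conversion happens only in `io`.
* Multi-chain PDB inputs concatenate into a single indexed trace in file
  order; residues lacking a P atom are skipped with a warning.
* The 18 Å gate compares the *current* distance, not the native one; the
  alternative reading would freeze escaped segments back, qualitatively
  changing the protocol.

## Known limitations

* The rigid-SSE approximation cannot represent intra-stem deformation; a
  real helix bends.
* Denaturation amplitude on small fixtures is modest (a few Å RMSD), so
  restriction effects are fractions of an ångström — detectable only due to
  the paired seeding design.
* Folding is geometric, not thermodynamic: no acceptance criterion, no
  temperature, no chirality preference.  Mirror-image folds are reported at
  their (poor) proper-rotation RMSD.
* The SimRNA restraint writer emits the file dialect only; running that
  simulator is out of scope.
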