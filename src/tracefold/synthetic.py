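"""Ideal-geometry toy RNA fixtures with planted contact predictions.

Builds self-avoiding phosphate traces for four topologies — a plain helix, a
stem-loop, a Y (two stem-loop arms on a trunk) and a cruciform (four arms) —
together with their base-pair sets and Gremlin-style scored contact lists with
a controllable mix of base pairs, planted true non-local contacts and planted
false contacts.  Stems use the same ideal duplex template the engine refines
toward, so built structures are fixed points of the refinement terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import _geometry as geom
from .errors import ConstructionError
from .io import ContactPrediction
from .structure import BasePair, Chain, SecondaryStructure, detect_sses
from .restraints import FALSE_THRESHOLD

#: Arm-axis separation in the Y topology (angstrom).
Y_ARM_SEPARATION = 30.0
#: Vertical gap between trunk top and arm bases in the Y topology (angstrom).
Y_TRUNK_GAP = 12.0
#: Inward tilt of the Y arm loops, so distal loops approach cross-link range.
Y_LOOP_TILT = np.deg2rad(20.0)
#: Radial offset of arm bases from the centre of a cruciform junction.
CRUCIFORM_RADIUS = 21.0


@dataclass(frozen=True)
class TopologySpec:
    """Recipe for a toy topology.

    ``stem_lengths`` orders stems 5' to 3' (for the Y the trunk comes first,
    then the two arms).  ``loop_lengths`` gives the hairpin loop sizes of the
    stem-loop arms.  ``cross_links`` requests planted distal contacts between
    the loops of the given arm indices (0-based, counting stem-loop arms).
    """

    kind: str
    stem_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...] = ()
    cross_links: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "stemloop", "Y", "cruciform"):
            raise ConstructionError(f"unknown topology kind {self.kind!r}")
        if any(s < 3 for s in self.stem_lengths):
            raise ConstructionError("every stem needs >= 3 base pairs to form an SSE")
        expected_arms = {"helix": 0, "stemloop": 1, "Y": 2, "cruciform": 4}[self.kind]
        expected_stems = {"helix": 1, "stemloop": 1, "Y": 3, "cruciform": 4}[self.kind]
        if len(self.stem_lengths) != expected_stems:
            raise ConstructionError(
                f"{self.kind} needs {expected_stems} stems, got {len(self.stem_lengths)}"
            )
        if len(self.loop_lengths) != expected_arms:
            raise ConstructionError(
                f"{self.kind} needs {expected_arms} loop lengths, got {len(self.loop_lengths)}"
            )
        if any(m < 2 for m in self.loop_lengths):
            raise ConstructionError("hairpin loops need >= 2 residues")


@dataclass(frozen=True)
class BuiltTopology:
    """A built fixture: trace, secondary structure, planted cross-link pairs."""

    chain: Chain
    ss: SecondaryStructure
    cross_links: tuple[BasePair, ...] = ()
    loop_ranges: tuple[tuple[int, int], ...] = field(default=(), repr=False)


def build_helix(n_bp: int) -> tuple[Chain, frozenset[BasePair]]:
    """An ideal ``n_bp`` duplex trace with pairs ``(k, 2 n_bp - 1 - k)``."""
    if n_bp < 3:
        raise ConstructionError("a helix fixture needs >= 3 base pairs")
    coords = geom.ideal_duplex(n_bp)
    pairs = frozenset(BasePair(k, 2 * n_bp - 1 - k) for k in range(n_bp))
    return Chain.from_coords(coords), pairs


def _arm(n_bp: int, loop_len: int, bulge: np.ndarray | None = None) -> np.ndarray:
    """Local coordinates of a stem-loop arm along +z.

    Chain order: stem strand A (indices ``0..n-1``), loop (``n..n+m-1``),
    stem strand B (``n+m..2n+m-1``).  The hairpin loop is a circular arc at
    bond spacing bowing toward ``bulge`` (default: up the helix axis).
    """
    duplex = geom.ideal_duplex(n_bp)
    if bulge is None:
        bulge = np.array([0.0, 0.0, 1.0])
    loop = geom.arc_points(duplex[n_bp - 1], duplex[n_bp], loop_len, bulge)
    return np.vstack([duplex[:n_bp], loop, duplex[n_bp:]])


def _arm_pairs(offset: int, n_bp: int, loop_len: int) -> list[BasePair]:
    total = 2 * n_bp + loop_len
    return [BasePair(offset + k, offset + total - 1 - k) for k in range(n_bp)]


def _place(coords: np.ndarray, about_z: float = 0.0, shift=(0.0, 0.0, 0.0)) -> np.ndarray:
    R = geom.rotation_about_axis(np.array([0.0, 0.0, 1.0]), about_z)
    return coords @ R.T + np.asarray(shift, dtype=float)


def _linker(
    a_prev: np.ndarray, a: np.ndarray, b: np.ndarray, b_next: np.ndarray
) -> np.ndarray:
    """Smooth connector from ``a`` to ``b``, tangent-matched to its neighbours."""
    chord = float(np.linalg.norm(b - a))
    n = geom.auto_points(chord)
    return geom.hermite_points(a, a - a_prev, b, b_next - b, n)


def build_stemloop(n_bp: int, loop_len: int) -> BuiltTopology:
    coords = _arm(n_bp, loop_len)
    pairs = _arm_pairs(0, n_bp, loop_len)
    chain = Chain.from_coords(coords)
    ss = SecondaryStructure.from_pairs(pairs, len(chain))
    return BuiltTopology(chain, ss, loop_ranges=((n_bp, n_bp + loop_len),))


def _spun_arm(
    n_bp: int,
    loop_len: int,
    spin: float,
    shift,
    bulge_global: np.ndarray | None = None,
) -> np.ndarray:
    """An arm spun about its own axis, its loop bowing toward ``bulge_global``."""
    bulge_local = None
    if bulge_global is not None:
        Rz = geom.rotation_about_axis(np.array([0.0, 0.0, 1.0]), -spin)
        bulge_local = Rz @ np.asarray(bulge_global, dtype=float)
    return _place(_arm(n_bp, loop_len, bulge=bulge_local), about_z=spin, shift=shift)


def _relax_flexible(
    coords: np.ndarray,
    pairs: list[BasePair],
    loops: tuple[tuple[int, int], ...],
    linked_loops: bool,
    iterations: int = 400,
    step: float = 0.3,
) -> np.ndarray:
    """Deterministically push loop/linker residues off sub-10 A contacts.

    Stem (SSE) atoms are frozen; the flexible residues are iterated under the
    engine's own bond-regularization (toward 6 A) and repulsion (under 10 A)
    rules until the draft geometry is self-avoiding.  Inter-loop pairs are
    left untouched when a cross-link between the loops is part of the design.
    """
    from .engine import SimConfig, _step_bonded, _step_repulsion

    coords = coords.copy()
    L = len(coords)
    cfg = SimConfig(step=step)
    sse_id = np.full(L, -1)
    for k, sse in enumerate(detect_sses(pairs)):
        sse_id[sse.members] = k
    frozen = sse_id >= 0
    loop_id = np.full(L, -1)
    for k, (lo, hi) in enumerate(loops):
        loop_id[lo:hi] = k
    iu, ju = np.triu_indices(L, k=2)
    same = (sse_id[iu] >= 0) & (sse_id[iu] == sse_id[ju])
    excl = same
    if linked_loops:
        inter = (loop_id[iu] >= 0) & (loop_id[ju] >= 0) & (loop_id[iu] != loop_id[ju])
        excl = same | inter
    rep_I, rep_J = iu[~excl], ju[~excl]
    anchor = coords[frozen].copy()
    for _ in range(iterations):
        _step_bonded(coords, cfg)
        coords[frozen] = anchor
        _step_repulsion(coords, rep_I, rep_J, cfg)
        coords[frozen] = anchor
    return coords


def _min_clearance(
    coords: np.ndarray, pairs: list[BasePair], loops: tuple[tuple[int, int], ...]
) -> tuple[float, float]:
    """(worst non-designed clearance, closest loop-loop distance) of a draft."""
    L = len(coords)
    sse_id = np.full(L, -1)
    for k, sse in enumerate(detect_sses(pairs)):
        sse_id[sse.members] = k
    iu, ju = np.triu_indices(L, k=2)
    d = squareform(pdist(coords))[iu, ju]
    same = (sse_id[iu] >= 0) & (sse_id[iu] == sse_id[ju])
    loop_id = np.full(L, -1)
    for k, (lo, hi) in enumerate(loops):
        loop_id[lo:hi] = k
    inter_loop = (loop_id[iu] >= 0) & (loop_id[ju] >= 0) & (loop_id[iu] != loop_id[ju])
    keep = ~(same | inter_loop)
    clearance = float(d[keep].min()) if keep.any() else np.inf
    loop_loop = float(d[inter_loop].min()) if inter_loop.any() else np.inf
    return clearance, loop_loop


def _build_y(spec: TopologySpec) -> BuiltTopology:
    """Two stem-loop arms side by side on a trunk.

    Each arm's spin about its own axis is a free parameter (it swings the
    hairpin loop's take-off direction and hence the loop apex); a
    deterministic grid search picks the feasible combination (self-avoiding;
    loops within cross-link range when one is requested) with the largest
    clearance.
    """
    trunk_bp, arm1_bp, arm2_bp = spec.stem_lengths
    m1, m2 = spec.loop_lengths
    D, gap = Y_ARM_SEPARATION, Y_TRUNK_GAP

    trunk = geom.ideal_duplex(trunk_bp)
    # orient the trunk so its strand-A top exit faces arm 1 (the -x side)
    rho = np.pi - (trunk_bp - 1) * geom.TWIST
    trunk = _place(trunk, about_z=rho, shift=(0.0, 0.0, -gap - (trunk_bp - 1) * geom.RISE))

    spins = np.linspace(0.0, 2.0 * np.pi, 12, endpoint=False)
    tilts = np.deg2rad([16.0, 24.0, 32.0, 40.0]) if spec.cross_links else [0.0]

    def assemble(tilt, s1, s2):
        bulge1 = np.array([np.sin(tilt), 0.0, np.cos(tilt)])   # leans toward +x
        bulge2 = np.array([-np.sin(tilt), 0.0, np.cos(tilt)])  # leans toward -x
        arm1 = _spun_arm(arm1_bp, m1, s1, (-D / 2.0, 0.0, 0.0), bulge1)
        arm2 = _spun_arm(arm2_bp, m2, s2, (D / 2.0, 0.0, 0.0), bulge2)
        link1 = _linker(trunk[trunk_bp - 2], trunk[trunk_bp - 1], arm1[0], arm1[1])
        link2 = _linker(arm1[-2], arm1[-1], arm2[0], arm2[1])
        link3 = _linker(arm2[-2], arm2[-1], trunk[trunk_bp], trunk[trunk_bp + 1])
        coords = np.vstack(
            [trunk[:trunk_bp], link1, arm1, link2, arm2, link3, trunk[trunk_bp:]]
        )
        L = len(coords)
        o1 = trunk_bp + len(link1)
        o2 = o1 + 2 * arm1_bp + m1 + len(link2)
        pairs = (
            [BasePair(k, L - 1 - k) for k in range(trunk_bp)]
            + _arm_pairs(o1, arm1_bp, m1)
            + _arm_pairs(o2, arm2_bp, m2)
        )
        loops = (
            (o1 + arm1_bp, o1 + arm1_bp + m1),
            (o2 + arm2_bp, o2 + arm2_bp + m2),
        )
        return coords, pairs, loops

    drafts = []
    for tilt in tilts:
        for s1 in spins:
            for s2 in spins:
                coords, pairs, loops = assemble(tilt, s1, s2)
                clearance, loop_loop = _min_clearance(coords, pairs, loops)
                if clearance < 8.0 or loop_loop < 10.0:
                    continue
                if spec.cross_links and loop_loop > 17.0:
                    continue
                drafts.append((clearance, loop_loop, coords, pairs, loops))
    coords, pairs, loops = _settle_drafts(drafts, bool(spec.cross_links), "Y")
    # (when a cross-link is requested the drafts are ranked so the planted
    # loop-loop contact sits just inside the 17 A restraint target, poised to
    # oppose outward denaturation)
    chain = Chain.from_coords(coords)
    ss = SecondaryStructure.from_pairs(pairs, len(chain))
    cross = _resolve_cross_links(chain, spec.cross_links, loops)
    return BuiltTopology(chain, ss, cross, loops)


def _settle_drafts(drafts, linked: bool, kind: str):
    """Relax the most promising draft arrangements and keep the clearest.

    Drafts already self-avoiding at 10 A are accepted as they stand; marginal
    ones get the frozen-stem relaxation first.  Cross-linked drafts are ranked
    by how close the loop-loop contact sits to the 17 A restraint target;
    plain drafts by clearance.  Raises if nothing settles.
    """
    if linked:
        drafts.sort(key=lambda d: (-d[1], -d[0]))
    else:
        drafts.sort(key=lambda d: -d[0])
    best = None
    for clearance, loop_loop, coords, pairs, loops in drafts[:12]:
        if clearance < 10.0:
            coords = _relax_flexible(coords, pairs, loops, linked_loops=linked)
            clearance, loop_loop = _min_clearance(coords, pairs, loops)
            bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            if np.abs(bonds - geom.BOND).max() > 0.2:
                continue
        if clearance < 10.0 or loop_loop < 10.0 or (linked and loop_loop > 17.0):
            continue
        score = loop_loop if linked else clearance
        if best is None or score > best[0] + 1e-9:
            best = (score, coords, pairs, loops)
    if best is None:
        raise ConstructionError(
            f"no self-avoiding {kind} arrangement found for this spec"
        )
    return best[1], best[2], best[3]


def _build_cruciform(spec: TopologySpec) -> BuiltTopology:
    """Four stem-loop arms pointing outward in a plane from a central junction.

    All arms share one spin angle about their own axes (preserving the 4-fold
    arrangement); a deterministic search over that spin and the junction
    radius picks the clearest self-avoiding configuration.
    """
    tip = geom.rotation_about_axis(np.array([0.0, 1.0, 0.0]), np.pi / 2.0)

    def assemble(rho, spin):
        segments: list[np.ndarray] = []
        offsets: list[int] = []
        pos = 0
        for k, (n, m) in enumerate(zip(spec.stem_lengths, spec.loop_lengths)):
            azimuth = k * np.pi / 2.0
            spin_m = geom.rotation_about_axis(np.array([0.0, 0.0, 1.0]), spin)
            azi_m = geom.rotation_about_axis(np.array([0.0, 0.0, 1.0]), azimuth)
            radial = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
            arm = _arm(n, m) @ spin_m.T @ tip.T @ azi_m.T + rho * radial
            if k > 0:
                prev = segments[-1]
                link = _linker(prev[-2], prev[-1], arm[0], arm[1])
                segments.append(link)
                pos += len(link)
            offsets.append(pos)
            segments.append(arm)
            pos += len(arm)
        coords = np.vstack(segments)
        pairs: list[BasePair] = []
        loops: list[tuple[int, int]] = []
        for k, (n, m) in enumerate(zip(spec.stem_lengths, spec.loop_lengths)):
            pairs.extend(_arm_pairs(offsets[k], n, m))
            loops.append((offsets[k] + n, offsets[k] + n + m))
        return coords, pairs, tuple(loops)

    drafts = []
    for rho in (CRUCIFORM_RADIUS, CRUCIFORM_RADIUS + 3.0, CRUCIFORM_RADIUS + 6.0):
        for spin in np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False):
            coords, pairs, loops = assemble(rho, spin)
            clearance, loop_loop = _min_clearance(coords, pairs, loops)
            if clearance < 8.0 or loop_loop < 10.0:
                continue
            drafts.append((clearance, loop_loop, coords, pairs, loops))
    coords, pairs, loops = _settle_drafts(drafts, bool(spec.cross_links), "cruciform")
    chain = Chain.from_coords(coords)
    ss = SecondaryStructure.from_pairs(pairs, len(chain))
    cross = _resolve_cross_links(chain, spec.cross_links, loops)
    return BuiltTopology(chain, ss, cross, loops)


def _resolve_cross_links(
    chain: Chain,
    requests: Iterable[tuple[int, int]],
    loops: tuple[tuple[int, int], ...],
) -> tuple[BasePair, ...]:
    """Pick, per requested arm pair, the closest loop-loop residue pair."""
    out = []
    for a, b in requests:
        if a >= len(loops) or b >= len(loops):
            raise ConstructionError(f"cross-link arms ({a}, {b}) out of range")
        ra, rb = loops[a], loops[b]
        best, best_d = None, np.inf
        for i in range(*ra):
            for j in range(*rb):
                d = float(np.linalg.norm(chain.coords[j] - chain.coords[i]))
                if d < best_d:
                    best, best_d = (min(i, j), max(i, j)), d
        if best is None or best_d > 17.0:
            raise ConstructionError(
                f"loops of arms {a} and {b} never approach within 17 A "
                f"(closest {best_d:.1f} A); cannot plant a cross-link"
            )
        out.append(BasePair(*best))
    return tuple(out)


def check_clearance(built: BuiltTopology, min_clear: float = 10.0) -> float:
    """Minimum distance over non-bonded, non-intra-SSE, non-cross-link pairs.

    Raises :class:`ConstructionError` if the trace approaches itself closer
    than ``min_clear`` outside the designed contacts.
    """
    coords = built.chain.coords
    L = len(coords)
    sse_id = np.full(L, -1)
    for k, sse in enumerate(detect_sses(built.ss.pairs)):
        sse_id[sse.members] = k
    iu, ju = np.triu_indices(L, k=2)
    d = squareform(pdist(coords))[iu, ju]
    same = (sse_id[iu] >= 0) & (sse_id[iu] == sse_id[ju])
    # exclude designed cross-link contacts: pairs spanning two cross-linked loops
    loop_id = np.full(L, -1)
    linked_arms = set()
    for p in built.cross_links:
        for k, (lo, hi) in enumerate(built.loop_ranges):
            if lo <= p.i < hi or lo <= p.j < hi:
                linked_arms.add(k)
    for k in linked_arms:
        lo, hi = built.loop_ranges[k]
        loop_id[lo:hi] = k
    designed = (loop_id[iu] >= 0) & (loop_id[ju] >= 0) & (loop_id[iu] != loop_id[ju])
    keep = ~(same | designed)
    worst = float(d[keep].min()) if keep.any() else np.inf
    if worst < min_clear - 1e-6:
        k = int(np.argmin(np.where(keep, d, np.inf)))
        raise ConstructionError(
            f"self-clash: residues {iu[k]} and {ju[k]} at {d[k]:.2f} A (< {min_clear})"
        )
    return worst


def build_topology(spec: TopologySpec, seed: int = 0) -> BuiltTopology:
    """Assemble a toy topology; deterministic for a given spec and seed.

    The built trace is validated to be self-avoiding (no non-bonded,
    non-intra-SSE approach under 10 angstrom) apart from the designed
    cross-link loop contacts, which must come within 17 angstrom.
    """
    del seed  # construction is fully deterministic; kept for interface parity
    if spec.kind == "helix":
        chain, pairs = build_helix(spec.stem_lengths[0])
        built = BuiltTopology(chain, SecondaryStructure.from_pairs(pairs, len(chain)))
    elif spec.kind == "stemloop":
        built = build_stemloop(spec.stem_lengths[0], spec.loop_lengths[0])
    elif spec.kind == "Y":
        built = _build_y(spec)
    else:
        built = _build_cruciform(spec)
    if spec.kind != "helix":
        check_clearance(built)
    return built


def synth_predictions(
    built: BuiltTopology,
    n_true_nonlocal: int = 0,
    n_false: int = 0,
    n_local: int | None = None,
    score_gap: float = 1.0,
    seed: int = 0,
    nonlocal_first: bool = True,
) -> tuple[list[ContactPrediction], dict[BasePair, str]]:
    """A ranked, scored contact table with known planted composition.

    Base pairs of the structure score high, planted true non-local contacts
    (the built cross-links) score higher still when ``nonlocal_first`` (the
    strong-covariation case) or just below the pairs otherwise, and ``n_false``
    random pairs with native distance over 21 angstrom score lowest.  Returns
    the ranked predictions and a ground-truth label per pair
    (``local`` / ``non_local`` / ``false``).
    """
    chain, ss = built.chain, built.ss
    rng = np.random.default_rng(seed)
    if n_true_nonlocal > len(built.cross_links):
        raise ConstructionError(
            f"{n_true_nonlocal} true non-local contacts requested but only "
            f"{len(built.cross_links)} cross-links were built"
        )
    locals_ = sorted(ss.pairs)[:n_local]
    nonlocals = list(built.cross_links[:n_true_nonlocal])
    falses = _plant_false_pairs(chain, ss, n_false, rng)

    scored: list[tuple[BasePair, float, str]] = []
    top = 2.0 * score_gap + 3.0
    if nonlocal_first:
        groups = [(nonlocals, "non_local"), (locals_, "local"), (falses, "false")]
    else:
        groups = [(locals_, "local"), (nonlocals, "non_local"), (falses, "false")]
    level = top
    for members, label in groups:
        for k, p in enumerate(members):
            scored.append((p, level - 0.01 * k, label))
        level -= score_gap
    scored.sort(key=lambda t: (-t[1], t[0]))
    preds = [
        ContactPrediction(p.i, p.j, score, rank=r + 1)
        for r, (p, score, _) in enumerate(scored)
    ]
    labels = {p: label for p, _, label in scored}
    return preds, labels


def _plant_false_pairs(
    chain: Chain, ss: SecondaryStructure, n: int, rng: np.random.Generator
) -> list[BasePair]:
    """Random pairs with native distance > 21 A, not base-paired, sep >= 4."""
    if n == 0:
        return []
    L = len(chain)
    dmat = chain.distance_matrix()
    candidates = [
        BasePair(i, j)
        for i in range(L)
        for j in range(i + 4, L)
        if dmat[i, j] > FALSE_THRESHOLD and BasePair(i, j) not in ss.pairs
    ]
    if len(candidates) < n:
        raise ConstructionError(
            f"cannot plant {n} false pairs: only {len(candidates)} candidates "
            f"beyond {FALSE_THRESHOLD} A"
        )
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[k] for k in sorted(idx)]
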