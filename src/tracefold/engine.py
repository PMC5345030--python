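"""The coarse-grained phosphate-trace simulator.

Each nucleotide is a single point (its phosphate).  Ladders of >= 3
consecutive base pairs are rigid secondary-structure elements (SSEs): on every
cycle each SSE is displaced and rotated randomly by a small amount, and a set
of geometric refinement terms then each move atom pairs by at most a fixed
step (0.5 angstrom by default):

* SSE internal geometry is refined toward an ideal duplex template,
* consecutive phosphate virtual bonds are refined toward 6 angstrom,
* local distances within a 10-residue window are refined toward their values
  in the starting structure, but only while the current distance is under
  18 angstrom (so large conformational changes remain acceptable),
* restrained pairs above the 17 angstrom target separation are contracted
  (one-sided: pairs at or below target are never touched),
* non-bonded, non-excluded pairs closer than 10 angstrom are repelled.

Shifts are applied symmetrically to both atoms of a pair; per-atom net
displacements from a term are capped at the step size.  With a fixed seed a
run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._geometry import rotation_about_axis
from .structure import BasePair, Chain, SSE, SecondaryStructure, detect_sses

_FALLBACK_AXIS = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class SimConfig:
    """Engine parameters.

    Lengths are in angstrom, rotations in radians.  ``perturb_rotation`` is
    numerically coupled to ``perturb_translation`` when left unset, matching
    the coupled sweep of both levels.
    """

    cycles: int = 1000
    perturb_translation: float = 0.08
    perturb_rotation: float | None = None
    bond_ideal: float = 6.0
    repel_below: float = 10.0
    local_window: int = 10
    local_gate: float = 18.0
    restraint_target: float = 17.0
    step: float = 0.5
    replicates: int = 10
    seed: int = 0
    diagnostics: bool = False

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.local_window < 2:
            raise ValueError("local_window must be >= 2")
        for name in ("bond_ideal", "repel_below", "local_gate", "restraint_target", "step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.perturb_translation < 0:
            raise ValueError("perturb_translation must be >= 0")

    @property
    def rotation_level(self) -> float:
        return (
            self.perturb_translation
            if self.perturb_rotation is None
            else self.perturb_rotation
        )


@dataclass
class RunResult:
    """Final models of a simulation plus optional per-cycle diagnostics."""

    models: list[Chain]
    diagnostics: dict[str, list] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shared pair-shift machinery


def _unit_vectors(coords: np.ndarray, I: np.ndarray, J: np.ndarray):
    vec = coords[J] - coords[I]
    d = np.linalg.norm(vec, axis=1)
    u = np.empty_like(vec)
    ok = d > 1e-12
    u[ok] = vec[ok] / d[ok, None]
    u[~ok] = _FALLBACK_AXIS  # deterministic axis for coincident points
    return d, u


def _apply_deltas(
    coords: np.ndarray,
    I: np.ndarray,
    J: np.ndarray,
    delta: np.ndarray,
    u: np.ndarray,
    step: float,
    average: bool = False,
) -> None:
    """Shift each pair's atoms symmetrically to change its distance by ``delta``.

    Per-atom contributions are summed (or averaged over the atom's active
    pairs when ``average``) and the net per-atom displacement capped at
    ``step``.  Operates in place.
    """
    if len(I) == 0:
        return
    disp = np.zeros_like(coords)
    half = 0.5 * delta[:, None] * u
    np.add.at(disp, J, half)
    np.add.at(disp, I, -half)
    if average:
        counts = np.zeros(len(coords))
        active = (np.abs(delta) > 1e-12).astype(float)
        np.add.at(counts, J, active)
        np.add.at(counts, I, active)
        counts[counts == 0] = 1.0
        disp /= counts[:, None]
    norms = np.linalg.norm(disp, axis=1)
    over = norms > step
    if np.any(over):
        disp[over] *= (step / norms[over])[:, None]
    coords += disp


# ---------------------------------------------------------------------------
# refinement steps (public wrappers operate on Chain objects)


def _step_bonded(coords: np.ndarray, config: SimConfig) -> None:
    L = len(coords)
    I = np.arange(L - 1)
    J = I + 1
    d, u = _unit_vectors(coords, I, J)
    delta = np.clip(config.bond_ideal - d, -config.step, config.step)
    _apply_deltas(coords, I, J, delta, u, config.step, average=True)


def step_bonded(chain: Chain, config: SimConfig = SimConfig()) -> Chain:
    """Refine consecutive phosphate bonds toward the 6 angstrom ideal."""
    coords = chain.coords.copy()
    _step_bonded(coords, config)
    return chain.with_coords(coords)


def _step_repulsion(
    coords: np.ndarray, I: np.ndarray, J: np.ndarray, config: SimConfig
) -> None:
    d, u = _unit_vectors(coords, I, J)
    active = d < config.repel_below
    if not np.any(active):
        return
    delta = np.full(active.sum(), config.step)
    _apply_deltas(coords, I[active], J[active], delta, u[active], config.step)


def step_repulsion(
    chain: Chain,
    config: SimConfig = SimConfig(),
    excluded_pairs: Iterable[tuple[int, int]] = (),
) -> Chain:
    """Push apart non-bonded phosphate pairs closer than 10 angstrom.

    ``excluded_pairs`` should contain intra-SSE pairs and active restraint
    pairs; bonded neighbours (sequence separation < 2) are always excluded.
    """
    L = len(chain)
    excl = {(min(i, j), max(i, j)) for i, j in excluded_pairs}
    pairs = [
        (i, j)
        for i in range(L)
        for j in range(i + 2, L)
        if (i, j) not in excl
    ]
    coords = chain.coords.copy()
    if pairs:
        I, J = np.array(pairs).T
        _step_repulsion(coords, I, J, config)
    return chain.with_coords(coords)


def _step_local_window(
    coords: np.ndarray,
    I: np.ndarray,
    J: np.ndarray,
    native: np.ndarray,
    config: SimConfig,
) -> None:
    d, u = _unit_vectors(coords, I, J)
    active = d < config.local_gate
    if not np.any(active):
        return
    delta = np.clip(native[active] - d[active], -config.step, config.step)
    _apply_deltas(coords, I[active], J[active], delta, u[active], config.step, average=True)


def local_window_pairs(
    chain: Chain, config: SimConfig = SimConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays and native distances for all within-window pairs.

    Pairs with sequence separation 2 .. ``local_window - 1`` (virtual bonds
    have their own term); native distances are taken from ``chain``.
    """
    L = len(chain)
    I, J = [], []
    for sep in range(2, config.local_window):
        I.extend(range(L - sep))
        J.extend(range(sep, L))
    I = np.array(I, dtype=int)
    J = np.array(J, dtype=int)
    native = np.linalg.norm(chain.coords[J] - chain.coords[I], axis=1)
    return I, J, native


def step_local_window(
    chain: Chain,
    native_local_distances: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: SimConfig = SimConfig(),
) -> Chain:
    """Refine within-window distances toward their starting-structure values.

    Only applied while the current distance is under the 18 angstrom gate, so
    segments that have escaped the window are free to keep moving.
    """
    I, J, native = native_local_distances
    coords = chain.coords.copy()
    _step_local_window(coords, I, J, native, config)
    return chain.with_coords(coords)


def _step_pair_restraints(
    coords: np.ndarray, I: np.ndarray, J: np.ndarray, config: SimConfig
) -> None:
    d, u = _unit_vectors(coords, I, J)
    active = d > config.restraint_target
    if not np.any(active):
        return
    delta = -np.minimum(config.step, d[active] - config.restraint_target)
    _apply_deltas(coords, I[active], J[active], delta, u[active], config.step)


def step_pair_restraints(
    chain: Chain,
    restraints: Iterable[tuple[int, int]],
    config: SimConfig = SimConfig(),
) -> Chain:
    """Contract restrained pairs toward the 17 angstrom target separation.

    One-sided: pairs at or below the target are never moved, and every
    restraint is applied the same way whether local or non-local.
    """
    pairs = [(int(i), int(j)) for i, j in restraints]
    coords = chain.coords.copy()
    if pairs:
        I, J = np.array(pairs).T
        _step_pair_restraints(coords, I, J, config)
    return chain.with_coords(coords)


def _sse_pair_arrays(sses: Sequence[SSE]):
    """Concatenated (I, J, target) arrays over all intra-SSE pairs."""
    Is, Js, Ts = [], [], []
    for sse in sses:
        m = sse.members
        n = len(m)
        iu, ju = np.triu_indices(n, k=1)
        Is.append(m[iu])
        Js.append(m[ju])
        Ts.append(sse.ideal_distances[iu, ju])
    if not Is:
        return (np.empty(0, dtype=int),) * 2 + (np.empty(0),)
    return np.concatenate(Is), np.concatenate(Js), np.concatenate(Ts)


def _step_sse_ideal(
    coords: np.ndarray,
    I: np.ndarray,
    J: np.ndarray,
    target: np.ndarray,
    config: SimConfig,
) -> None:
    if len(I) == 0:
        return
    d, u = _unit_vectors(coords, I, J)
    delta = np.clip(target - d, -config.step, config.step)
    _apply_deltas(coords, I, J, delta, u, config.step, average=True)


def step_sse_ideal(
    chain: Chain, sses: Sequence[SSE], config: SimConfig = SimConfig()
) -> Chain:
    """Refine each SSE's internal pairwise distances toward its ideal template.

    Per-atom corrections are averaged over the atom's deviating pairs, a
    Jacobi-style distance-geometry step that converges without overshoot.
    """
    I, J, target = _sse_pair_arrays(sses)
    coords = chain.coords.copy()
    _step_sse_ideal(coords, I, J, target, config)
    return chain.with_coords(coords)


# ---------------------------------------------------------------------------
# random SSE perturbation


def _perturb_sses(
    coords: np.ndarray,
    sses: Sequence[SSE],
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    tmax = config.perturb_translation
    rmax = config.rotation_level
    for sse in sses:
        direction = _random_unit(rng)
        translation = rng.uniform(0.0, tmax) * direction
        axis = _random_unit(rng)
        angle = rng.uniform(0.0, rmax)
        if angle == 0.0 and not np.any(translation):
            continue  # keep the zero-level run an exact no-op
        m = sse.members
        centroid = coords[m].mean(axis=0)
        R = rotation_about_axis(axis, angle)
        coords[m] = (coords[m] - centroid) @ R.T + centroid + translation


def perturb_sses(
    chain: Chain,
    sses: Sequence[SSE],
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
) -> Chain:
    """Rigidly displace and rotate each SSE by a small random amount.

    Translation magnitude is uniform in ``[0, perturb_translation]`` along a
    random direction; rotation is about a random axis through the SSE centroid
    with angle uniform in ``[0, rotation_level]``.  Loop residues are not
    directly displaced.  Intra-SSE distances are preserved (rigid motion).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    coords = chain.coords.copy()
    _perturb_sses(coords, sses, config, rng)
    return chain.with_coords(coords)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


# ---------------------------------------------------------------------------
# full simulation


def make_circle_start(L: int, config: SimConfig = SimConfig()) -> Chain:
    """Extended circular starting conformation for folding runs.

    ``L`` points equally spaced on a circle of circumference ``bond_ideal * L``
    in the xy plane, so consecutive chords are just under the bond ideal.
    """
    if L < 3:
        raise ValueError("a circular start needs L >= 3")
    radius = config.bond_ideal * L / (2.0 * np.pi)
    theta = 2.0 * np.pi * np.arange(L) / L
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(L)]
    )
    return Chain.from_coords(coords)


def simulate(
    chain: Chain,
    ss: SecondaryStructure | Iterable[BasePair],
    restraints: Iterable[tuple[int, int]] = (),
    config: SimConfig = SimConfig(),
) -> RunResult:
    """Run the full perturb-and-refine cycle and return the final ensemble.

    Per replicate a generator is derived deterministically from
    ``config.seed``; each cycle applies, in order: random SSE perturbation,
    SSE ideal-geometry refinement, bond refinement, the gated local-window
    term, one-sided pair restraints, and non-bonded repulsion.  The local
    window is anchored to the *input* chain's distances.
    """
    pairs = ss.pairs if isinstance(ss, SecondaryStructure) else frozenset(
        BasePair(*p) for p in ss
    )
    sses = detect_sses(pairs)
    sse_I, sse_J, sse_T = _sse_pair_arrays(sses)

    L = len(chain)
    win_I, win_J, win_native = local_window_pairs(chain, config)

    rest_pairs = sorted({(min(i, j), max(i, j)) for i, j in restraints})
    if rest_pairs:
        rest_I, rest_J = np.array(rest_pairs, dtype=int).T
    else:
        rest_I = rest_J = np.empty(0, dtype=int)

    # repulsion acts on pairs with sequence separation >= 2 that are neither
    # within one SSE nor restrained (those terms own their distances)
    sse_id = np.full(L, -1)
    for k, sse in enumerate(sses):
        sse_id[sse.members] = k
    iu, ju = np.triu_indices(L, k=2)
    same_sse = (sse_id[iu] >= 0) & (sse_id[iu] == sse_id[ju])
    restrained = np.zeros(len(iu), dtype=bool)
    if rest_pairs:
        rest_set = set(rest_pairs)
        restrained = np.fromiter(
            ((int(a), int(b)) in rest_set for a, b in zip(iu, ju)),
            dtype=bool,
            count=len(iu),
        )
    keep = ~(same_sse | restrained)
    rep_I, rep_J = iu[keep], ju[keep]

    models: list[Chain] = []
    diagnostics: dict[str, list] = {"mean_bond": [], "restraints_satisfied": []}
    for rep in range(config.replicates):
        rng = np.random.default_rng([int(config.seed), rep])
        coords = chain.coords.copy()
        for _ in range(config.cycles):
            _perturb_sses(coords, sses, config, rng)
            _step_sse_ideal(coords, sse_I, sse_J, sse_T, config)
            _step_bonded(coords, config)
            _step_local_window(coords, win_I, win_J, win_native, config)
            if len(rest_I):
                _step_pair_restraints(coords, rest_I, rest_J, config)
            if len(rep_I):
                _step_repulsion(coords, rep_I, rep_J, config)
            if config.diagnostics:
                bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
                diagnostics["mean_bond"].append(float(bonds.mean()))
                if len(rest_I):
                    sep = np.linalg.norm(coords[rest_J] - coords[rest_I], axis=1)
                    diagnostics["restraints_satisfied"].append(
                        int((sep <= config.restraint_target + config.step).sum())
                    )
        models.append(chain.with_coords(coords))
    return RunResult(models=models, diagnostics=diagnostics if config.diagnostics else {})
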