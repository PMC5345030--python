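"""Deviation measures between phosphate-trace models and a native structure.

* ``superpose_rmsd`` — RMSD after least-squares rigid-body superposition
  (proper rotations only, the standard structural-biology convention).
* ``drmsd`` — root-mean-square deviation over all pairwise internal distances;
  superposition-free and blind to reflection.
* ``drmsd_max`` — dRMSD of the per-pair maximum-distance matrix of an ensemble
  against the native distance matrix; captures the full extent to which the
  structure was free to deviate, not just the ensemble mean.
* ``per_residue_rmsd`` — deviation profile along the sequence, useful for
  spotting which segments a restraint set actually pins down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import Chain


@dataclass(frozen=True)
class MetricSummary:
    """Ensemble-level deviation summary (all values in angstrom)."""

    rmsd_mean: float
    drmsd_mean: float
    drmsd_max: float
    per_residue: np.ndarray

    @classmethod
    def from_ensemble(cls, models: Sequence[Chain], native: Chain) -> "MetricSummary":
        return cls(
            rmsd_mean=float(np.mean([superpose_rmsd(m, native) for m in models])),
            drmsd_mean=float(np.mean([drmsd(m, native) for m in models])),
            drmsd_max=drmsd_max(models, native),
            per_residue=per_residue_rmsd(models, native),
        )


def _check_lengths(a: Chain, b: Chain, minimum: int = 2) -> None:
    if len(a) != len(b):
        raise ValueError(f"chain lengths differ: {len(a)} vs {len(b)}")
    if len(a) < minimum:
        raise ValueError(f"need at least {minimum} residues")


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred ``P`` onto centred ``Q``."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: Chain, target: Chain) -> Chain:
    """Rigid-body superposition of ``mobile`` onto ``target`` (least squares)."""
    _check_lengths(mobile, target, minimum=3)
    P = mobile.coords - mobile.coords.mean(axis=0)
    Q = target.coords - target.coords.mean(axis=0)
    R = kabsch_rotation(P, Q)
    return mobile.with_coords(P @ R.T + target.coords.mean(axis=0))


def superpose_rmsd(a: Chain, b: Chain) -> float:
    """RMSD between equivalent phosphates after optimal rigid superposition."""
    _check_lengths(a, b, minimum=3)
    P = a.coords - a.coords.mean(axis=0)
    Q = b.coords - b.coords.mean(axis=0)
    R = kabsch_rotation(P, Q)
    return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))


def drmsd(a: Chain, b: Chain) -> float:
    """Distance-based RMSD over all ``n (n - 1) / 2`` phosphate pairs.

    Root-mean-square of the per-pair distance deviations, so values are
    comparable across molecules of different length.
    """
    _check_lengths(a, b)
    da = pdist(a.coords)
    db = pdist(b.coords)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def max_distance_matrix(models: Sequence[Chain]) -> np.ndarray:
    """Entrywise maximum of the models' phosphate distance matrices."""
    if not models:
        raise ValueError("need at least one model")
    L = len(models[0])
    for m in models:
        if len(m) != L:
            raise ValueError("models have mismatched lengths")
    stacked = np.stack([pdist(m.coords) for m in models])
    return squareform(stacked.max(axis=0))


def drmsd_max(models: Sequence[Chain], native: Chain) -> float:
    """dRMSD between the ensemble's maximum-distance matrix and the native.

    The per-pair maximum over models replaces a single model's distances in
    the dRMSD formula.  A secondary convention — the maximum of the per-model
    dRMSDs — is available as ``max(drmsd(m, native) for m in models)``.
    """
    mdm = max_distance_matrix(models)
    if mdm.shape[0] != len(native):
        raise ValueError("ensemble and native lengths differ")
    iu = np.triu_indices(len(native), k=1)
    diff = mdm[iu] - native.distance_matrix()[iu]
    return float(np.sqrt(np.mean(diff**2)))


def per_residue_rmsd(models: Sequence[Chain], native: Chain) -> np.ndarray:
    """Per-position RMS deviation across globally superposed models.

    Each model is first superposed onto the native as a whole; the profile at
    position ``i`` is the root-mean-square of that residue's displacement over
    the ensemble.
    """
    sq = np.zeros(len(native))
    for m in models:
        aligned = superpose(m, native)
        sq += np.sum((aligned.coords - native.coords) ** 2, axis=1)
    return np.sqrt(sq / len(models))
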