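"""Restraint-set construction: ranking, truncation, classification, cutoffs.

A contact-prediction method yields a ranked, scored list of candidate pairs.
Only the strongest few are worth imposing as distance restraints; the default
selection rule keeps ``N = 5 + L/4`` contacts for a molecule of length ``L``
(an error-rate-motivated reduction of the simpler ``L/3`` rule).  Each selected
contact is classified against the known structure:

* ``shared_local`` — also found in the thermodynamically predicted pair set,
* ``extra_local`` — a further observed nested base pair,
* ``non_local`` — neither, but native phosphate distance <= 21 angstrom,
* ``false`` — native phosphate distance over 21 angstrom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .io import ContactPrediction
from .structure import BasePair, Chain, SecondaryStructure, pair_distance

logger = logging.getLogger(__name__)

CATEGORIES = ("shared_local", "extra_local", "non_local", "false")

#: Native phosphate-phosphate distance separating true non-local contacts from
#: false ones (angstrom).  A distance of exactly 21 is still non-local.
FALSE_THRESHOLD = 21.0


@dataclass(frozen=True)
class CutoffRule:
    """The linear restraint-count rule ``N = intercept + L / divisor``.

    ``comparison_line_divisor`` is the simpler all-base-pairs comparison line
    (count ~ L/3) that the default rule undercuts.
    """

    intercept: int = 5
    divisor: int = 4
    comparison_line_divisor: int = 3

    def __post_init__(self) -> None:
        if self.intercept < 0 or self.divisor <= 0:
            raise ValueError("intercept must be >= 0 and divisor > 0")


DEFAULT_RULE = CutoffRule()


@dataclass(frozen=True)
class RestraintSet:
    """An ordered, categorized restraint list with its engine target distance."""

    entries: tuple[ContactPrediction, ...]
    source: str = "predicted"
    target_distance: float = 17.0

    def __post_init__(self) -> None:
        if self.source not in ("observed", "rnafold", "predicted"):
            raise ValueError(f"unknown restraint source {self.source!r}")
        ranks = [e.rank for e in self.entries]
        if ranks != sorted(ranks):
            raise ValueError("restraint entries must be ordered by rank")

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> list[BasePair]:
        return [e.pair for e in self.entries]


def cutoff_count(L: int, rule: CutoffRule = DEFAULT_RULE) -> int:
    """Number of top-ranked contacts to keep for a molecule of length ``L``."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return rule.intercept + L // rule.divisor


def select_top(
    predictions: Sequence[ContactPrediction],
    L: int,
    rule: CutoffRule = DEFAULT_RULE,
) -> RestraintSet:
    """Keep the first ``cutoff_count(L)`` ranked predictions as restraints."""
    n = cutoff_count(L, rule)
    if len(predictions) < n:
        logger.warning(
            "only %d predictions available for a cutoff of %d; keeping all",
            len(predictions), n,
        )
    return RestraintSet(tuple(predictions[:n]), source="predicted")


def classify(
    predictions: Iterable[ContactPrediction],
    native: Chain,
    observed: SecondaryStructure,
    rnafold_pairs: Iterable[BasePair],
    false_threshold: float = FALSE_THRESHOLD,
) -> list[ContactPrediction]:
    """Attach a category to every prediction (see module docstring).

    Precedence: membership in the thermodynamically predicted (rnafold) set
    wins over membership in the observed nested set; otherwise the native
    phosphate distance decides between non-local and false.
    """
    rnafold = {BasePair(*p) for p in rnafold_pairs}
    out = []
    for p in predictions:
        if p.j >= len(native):
            raise IndexError(f"contact ({p.i}, {p.j}) out of range for L={len(native)}")
        if p.pair in rnafold:
            cat = "shared_local"
        elif p.pair in observed.nested:
            cat = "extra_local"
        elif pair_distance(native, p.pair) <= false_threshold:
            cat = "non_local"
        else:
            cat = "false"
        out.append(replace(p, category=cat))
    return out


def error_rate_cutoff(
    predictions: Sequence[ContactPrediction], max_error_fraction: float
) -> int:
    """Largest prefix length whose false fraction stays within the budget.

    Returns the largest ``k`` such that the number of ``false``-labelled
    entries among the top ``k`` divided by ``k`` is at most
    ``max_error_fraction``; 0 if no prefix qualifies.
    """
    if not 0.0 <= max_error_fraction <= 1.0:
        raise ValueError("max_error_fraction must be in [0, 1]")
    for p in predictions:
        if p.category is None:
            raise ValueError("predictions must be classified first")
    best = 0
    false_count = 0
    for k, p in enumerate(predictions, start=1):
        if p.category == "false":
            false_count += 1
        if false_count <= max_error_fraction * k:
            best = k
    return best


def incremental_sets(restraints: RestraintSet) -> list[RestraintSet]:
    """Rank-order prefixes of sizes 0, 1, ..., N of a restraint set.

    Restraints are introduced in ranked order of their predicted confidence,
    beginning with the strongest pairs; subset ``k`` is a prefix of subset
    ``k + 1``.
    """
    return [
        RestraintSet(
            restraints.entries[:k],
            source=restraints.source,
            target_distance=restraints.target_distance,
        )
        for k in range(len(restraints) + 1)
    ]
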