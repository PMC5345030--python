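"""Readers and writers for the package's text formats.

Supported formats:

* PDB phosphate traces (``ATOM`` records, one P atom per residue; ensembles as
  ``MODEL``/``ENDMDL`` blocks),
* dot-bracket secondary-structure strings with ``()[]{}<>`` layers,
* whitespace-separated contact tables ``i  j  score`` (1-based positions),
* SimRNA distance-restraint files (``WELL``/``SLOPE`` lines).

Residue numbering is 1-based in every on-disk format and converted to 0-based
indices at this boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import EmptyChainError, ParseError
from .structure import BasePair, Chain

logger = logging.getLogger(__name__)

_OPEN = "([{<"
_CLOSE = ")]}>"


@dataclass(frozen=True)
class ContactPrediction:
    """A scored candidate contact between residues ``i < j`` (0-based).

    ``rank`` is the 1-based position after sorting by descending score.
    ``category`` is filled in by the classifier: one of ``shared_local``,
    ``extra_local``, ``non_local`` or ``false``.
    """

    i: int
    j: int
    score: float
    rank: int = 0
    category: str | None = None

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ParseError(f"contact must have i < j, got ({self.i}, {self.j})")

    @property
    def pair(self) -> BasePair:
        return BasePair(self.i, self.j)


# ---------------------------------------------------------------------------
# PDB phosphate traces


def read_phosphate_trace(pdb_text: str) -> Chain:
    """Extract a phosphate trace (one P atom per residue) from PDB text.

    Residues without a P atom are skipped with a warning; ordering follows the
    file.  Multiple chains are concatenated into one indexed trace.  Only the
    first model of a multi-model file is read (use :func:`read_ensemble` for
    ensembles).
    """
    chains = read_ensemble(pdb_text)
    return chains[0]


def read_ensemble(pdb_text: str) -> list[Chain]:
    """Read every model of a (possibly multi-model) PDB file as a Chain."""
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("trace", StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"malformed PDB input: {exc}") from exc
    models: list[Chain] = []
    for model in structure:
        ids: list[tuple[str, int]] = []
        coords: list[np.ndarray] = []
        for chain in model:
            for residue in chain:
                if "P" in residue:
                    ids.append((chain.id, residue.id[1]))
                    coords.append(residue["P"].get_coord().astype(float))
                else:
                    logger.warning(
                        "residue %s %s%s has no P atom; skipped",
                        residue.get_resname(), chain.id, residue.id[1],
                    )
        if ids:
            models.append(Chain(tuple(ids), np.array(coords)))
    if not models:
        raise EmptyChainError("no phosphate (P) atoms found in PDB input")
    return models


def write_phosphate_trace(chain: Chain) -> str:
    """Render a chain as PDB ATOM records (P atoms only)."""
    return "".join(_atom_lines(chain)) + "END\n"


def write_ensemble(models: Sequence[Chain]) -> str:
    """Render an ensemble of chains as a multi-model PDB file."""
    out: list[str] = []
    for m, chain in enumerate(models, start=1):
        out.append(f"MODEL     {m:4d}\n")
        out.extend(_atom_lines(chain))
        out.append("ENDMDL\n")
    out.append("END\n")
    return "".join(out)


def _atom_lines(chain: Chain) -> list[str]:
    lines = []
    for serial, ((cid, resnum), xyz) in enumerate(zip(chain.ids, chain.coords), start=1):
        x, y, z = xyz
        lines.append(
            f"ATOM  {serial:5d}  P     N {cid:1s}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P\n"
        )
    return lines


# ---------------------------------------------------------------------------
# Dot-bracket


def parse_dotbracket(text: str) -> frozenset[BasePair]:
    """Parse a dot-bracket string into a base-pair set (0-based indices).

    ``()`` is the primary layer; ``[]``, ``{}`` and ``<>`` hold crossing
    (pseudoknot) pairs.  Dots are unpaired.
    """
    text = text.strip()
    stacks: list[list[int]] = [[] for _ in _OPEN]
    pairs: list[BasePair] = []
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(pos)
        elif ch in _CLOSE:
            layer = _CLOSE.index(ch)
            if not stacks[layer]:
                raise ParseError(f"unbalanced {ch!r} at position {pos}")
            pairs.append(BasePair(stacks[layer].pop(), pos))
        else:
            raise ParseError(f"unexpected character {ch!r} at position {pos}")
    for layer, stack in enumerate(stacks):
        if stack:
            raise ParseError(
                f"unbalanced {_OPEN[layer]!r} opened at position {stack[-1]}"
            )
    return frozenset(pairs)


def to_dotbracket(pairs: Iterable[BasePair], length: int) -> str:
    """Render a base-pair set as a dot-bracket string of ``length`` characters.

    Crossing pairs are assigned greedily to the first bracket layer in which
    they do not cross any pair already placed there.
    """
    layers: list[list[BasePair]] = [[]]
    for p in sorted(pairs):
        placed = False
        for layer in layers:
            if not any(q.i < p.i < q.j < p.j or p.i < q.i < p.j < q.j for q in layer):
                layer.append(p)
                placed = True
                break
        if not placed:
            if len(layers) == len(_OPEN):
                raise ParseError("more than 4 crossing layers; cannot render brackets")
            layers.append([p])
    chars = ["."] * length
    for level, layer in enumerate(layers):
        for p in layer:
            if p.j >= length:
                raise ParseError(f"pair {p} exceeds string length {length}")
            chars[p.i] = _OPEN[level]
            chars[p.j] = _CLOSE[level]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Contact tables


def read_contact_table(tsv_text: str) -> list[ContactPrediction]:
    """Read a scored contact table (``i  j  score``, 1-based positions).

    Duplicate ``(i, j)`` rows keep the maximum score.  Output is sorted by
    descending score, ties broken by ascending ``(i, j)``, with ranks assigned
    from 1.
    """
    rows = []
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.replace(",", "\t").split()
        if lineno == 1 and not _is_number(fields[0]):
            continue  # header row
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected 'i j score', got {line!r}")
        try:
            i, j, score = int(fields[0]), int(fields[1]), float(fields[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        if i == j:
            raise ParseError(f"line {lineno}: contact with i == j ({i})")
        if i < 1 or j < 1:
            raise ParseError(f"line {lineno}: positions are 1-based, got ({i}, {j})")
        if i > j:
            i, j = j, i
        rows.append((i - 1, j - 1, score))
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["i", "j", "score"])
    df = df.groupby(["i", "j"], as_index=False)["score"].max()
    df = df.sort_values(
        ["score", "i", "j"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return [
        ContactPrediction(int(r.i), int(r.j), float(r.score), rank=k + 1)
        for k, r in enumerate(df.itertuples())
    ]


def write_contact_table(
    predictions: Sequence[ContactPrediction], annotated: bool = False
) -> str:
    """Render contacts as a TSV (1-based positions).

    With ``annotated=True`` the rank and category columns are included.
    """
    lines = []
    if annotated:
        lines.append("i\tj\tscore\trank\tcategory")
        for p in predictions:
            lines.append(
                f"{p.i + 1}\t{p.j + 1}\t{p.score:g}\t{p.rank}\t{p.category or 'NA'}"
            )
    else:
        for p in predictions:
            lines.append(f"{p.i + 1}\t{p.j + 1}\t{p.score:g}")
    return "\n".join(lines) + ("\n" if lines else "")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return not math.isnan(float(token))


# ---------------------------------------------------------------------------
# SimRNA restraint files


def write_simrna_restraints(
    pairs: Iterable[tuple[int, int]],
    chain_id: str = "A",
    well: tuple[float, float, float] = (5.0, 10.0, 5.0),
    slope: tuple[float, float, float] = (5.0, 10.0, 1.0),
) -> str:
    """Emit SimRNA distance restraints for predicted contacts.

    For each ``(i, j)`` pair (1-based residue numbers) one square-well line and
    one flanking V-shaped slope line are written against the pseudo-base
    centroid atom ``MB``, e.g.::

        WELL A/16/MB A/39/MB 5.0 10.0 5.0
        SLOPE A/16/MB A/39/MB 5.0 10.0 1.0
    """
    lines = []
    for i, j in pairs:
        atoms = f"{chain_id}/{i}/MB {chain_id}/{j}/MB"
        lines.append(f"WELL {atoms} {well[0]:.1f} {well[1]:.1f} {well[2]:.1f}")
        lines.append(f"SLOPE {atoms} {slope[0]:.1f} {slope[1]:.1f} {slope[2]:.1f}")
    return "\n".join(lines) + ("\n" if lines else "")
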