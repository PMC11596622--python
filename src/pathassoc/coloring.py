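"""Atom-coloring count features for compounds.

Each atom in a hydrogen-free molecular graph receives a canonical string
"color" per depth: the depth-0 color is the element symbol (with a ``+n`` /
``-n`` suffix for a nonzero formal charge), and the depth-``d`` color is the
atom's depth-``(d-1)`` color followed by the lexicographically sorted list
of ``order:neighbor-color`` pairs over its bonded neighbors, e.g.
``C(1:C,1:O)``.  Two atoms whose rooted neighborhoods are isomorphic up to
the depth receive identical colors, so the multiset of colors over all
depths is invariant under atom relabeling.  A compound's feature vector is
the count of each color in a shared, lexicographically ordered vocabulary.

With ``max_depth=AUTO`` the recursion stops at the first depth where the
partition of the molecule's atoms into color classes stops refining (the
classical refinement fixpoint).  An isolated atom's color never changes
with depth and is counted once.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .chemio import EmptyMoleculeError, Molecule

logger = logging.getLogger(__name__)

AUTO = "auto"
"""Sentinel: recurse until the atom partition stops refining."""


def _depth0_color(element: str, charge: int) -> str:
    if charge > 0:
        return f"{element}+{charge}"
    if charge < 0:
        return f"{element}-{-charge}"
    return element


def color_atoms(mol: Molecule, max_depth: int | str = AUTO) -> Counter[str]:
    """Return the multiset of atom colors over depths ``0..D``.

    ``D`` is ``max_depth`` if an integer, otherwise the partition-refinement
    fixpoint.  For each atom, a depth's color is skipped when it equals the
    previous depth's color (isolated atoms), so the per-atom contribution is
    one color per *distinct* neighborhood expansion.

    Raises
    ------
    EmptyMoleculeError
        ``mol`` has no atoms.
    ValueError
        Negative ``max_depth``.
    """
    if mol.n_atoms == 0:
        raise EmptyMoleculeError(f"{mol.compound_id}: cannot color an empty molecule")
    auto = max_depth == AUTO
    if not auto:
        if not isinstance(max_depth, (int, np.integer)) or max_depth < 0:
            raise ValueError(f"max_depth must be >= 0 or AUTO, got {max_depth!r}")

    adj = mol.neighbors()
    colors = [_depth0_color(el, chg) for el, chg in mol.atoms]
    out: Counter[str] = Counter(colors)

    n_classes = len(set(colors))
    depth = 0
    while True:
        if auto:
            if n_classes == mol.n_atoms:
                break
        elif depth >= max_depth:
            break
        depth += 1
        nxt = []
        for i in range(mol.n_atoms):
            if not adj[i]:
                nxt.append(colors[i])  # isolated atom: color is stable
                continue
            pairs = sorted(f"{order}:{colors[j]}" for j, order in adj[i])
            nxt.append(f"{colors[i]}({','.join(pairs)})")
        new_classes = len(set(nxt))
        if auto and new_classes == n_classes:
            break
        for i in range(mol.n_atoms):
            if nxt[i] != colors[i]:
                out[nxt[i]] += 1
        colors = nxt
        n_classes = new_classes
    return out


@dataclass(frozen=True)
class ColorVocabulary:
    """Ordered universe of atom colors shared by all compounds.

    The order is lexicographic, hence independent of the order in which
    compounds were presented.  ``index`` maps color to position ``0..n-1``.
    """

    colors: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.colors)}
        )

    @property
    def index(self) -> Mapping[str, int]:
        return self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.colors)

    def __contains__(self, color: str) -> bool:
        return color in self.index

    def save(self, path: str | Path) -> None:
        """One color per line; the line number is the column index."""
        Path(path).write_text("".join(c + "\n" for c in self.colors))

    @classmethod
    def load(cls, path: str | Path) -> "ColorVocabulary":
        lines = Path(path).read_text().splitlines()
        return cls(colors=tuple(lines))


def build_vocabulary(color_multisets: Iterable[Mapping[str, int]]) -> ColorVocabulary:
    """Union of all colors across compounds, lexicographically sorted.

    Stable under permutation of the input order.  Raises ``ValueError`` on
    an empty collection.
    """
    universe: set[str] = set()
    n = 0
    for ms in color_multisets:
        universe.update(ms)
        n += 1
    if n == 0:
        raise ValueError("cannot build a vocabulary from zero compounds")
    return ColorVocabulary(colors=tuple(sorted(universe)))


def featurize(colors: Mapping[str, int], vocab: ColorVocabulary) -> sparse.csr_matrix:
    """Count vector (1 x ``len(vocab)``) of a compound's color multiset.

    Colors absent from the vocabulary (novel compounds at inference time)
    are dropped with a logged warning.
    """
    idx: list[int] = []
    val: list[int] = []
    dropped = []
    for color, count in colors.items():
        pos = vocab.index.get(color)
        if pos is None:
            dropped.append(color)
        else:
            idx.append(pos)
            val.append(count)
    if dropped:
        logger.warning(
            "%d color(s) not in the vocabulary were dropped: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:5]) + ("..." if len(dropped) > 5 else ""),
        )
    mat = sparse.csr_matrix(
        (val, (np.zeros(len(idx), dtype=np.int64), idx)),
        shape=(1, len(vocab)),
        dtype=np.int64,
    )
    mat.sum_duplicates()
    return mat


def featurize_compounds(
    molecules: Sequence[Molecule],
    max_depth: int | str = AUTO,
    vocab: ColorVocabulary | None = None,
) -> tuple[list[str], sparse.csr_matrix, ColorVocabulary]:
    """Color every molecule and stack count vectors into one sparse matrix.

    When ``vocab`` is None it is built from these molecules.  Returns
    ``(compound_ids, matrix, vocab)`` with rows ordered as the input.
    """
    multisets = [color_atoms(m, max_depth) for m in molecules]
    if vocab is None:
        vocab = build_vocabulary(multisets)
    rows = [featurize(ms, vocab) for ms in multisets]
    matrix = sparse.vstack(rows, format="csr")
    return [m.compound_id for m in molecules], matrix, vocab
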