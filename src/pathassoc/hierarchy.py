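"""Three-level pathway hierarchy, annotation propagation, pathway features.

Pathways are organized in three levels: top categories (L1), subcategories
(L2) and individual pathways (L3); every L2's parent is an L1 and every
L3's parent is an L2.  Compounds carry *direct* annotations (usually to L3,
sometimes to L2).  Because a compound annotated to an individual pathway is
by definition associated with the categories above it, annotations are
propagated upward to ancestors before the cross-join, so positives exist at
every level.

A pathway's feature vector is the element-wise sum of the feature vectors
of its member compounds (those whose expanded annotation set contains the
pathway), restricted to the pathway feature vocabulary: the columns of the
compound vocabulary that are positive in at least one pathway.  A
pathway's *size* is the summed heavy-atom count of its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

LEVELS = ("L1", "L2", "L3")


@dataclass(frozen=True)
class PathwayNode:
    pathway_id: str
    name: str
    level: str
    parent_id: str | None


class HierarchyError(ValueError):
    """Structurally invalid hierarchy or annotations referencing it."""


@dataclass
class PathwayHierarchy:
    """Validated 3-level pathway tree.

    Invariants enforced on construction: unique ids; L1 nodes are roots;
    an L2's parent is an existing L1; an L3's parent is an existing L2.
    """

    nodes: list[PathwayNode]
    _by_id: dict[str, PathwayNode] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[str, PathwayNode] = {}
        for node in self.nodes:
            if node.pathway_id in by_id:
                raise HierarchyError(f"duplicate pathway id {node.pathway_id!r}")
            if node.level not in LEVELS:
                raise HierarchyError(
                    f"{node.pathway_id}: level must be one of {LEVELS}, "
                    f"got {node.level!r}"
                )
            by_id[node.pathway_id] = node
        for node in self.nodes:
            if node.level == "L1":
                if node.parent_id:
                    raise HierarchyError(
                        f"L1 pathway {node.pathway_id} must not have a parent"
                    )
                continue
            parent = by_id.get(node.parent_id or "")
            expected = "L1" if node.level == "L2" else "L2"
            if parent is None or parent.level != expected:
                raise HierarchyError(
                    f"{node.level} pathway {node.pathway_id} needs an existing "
                    f"{expected} parent, got {node.parent_id!r}"
                )
        self._by_id = by_id

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __len__(self) -> int:
        return len(self.nodes)

    def level_of(self, pathway_id: str) -> str:
        return self._by_id[pathway_id].level

    def parent_of(self, pathway_id: str) -> str | None:
        return self._by_id[pathway_id].parent_id

    def ancestors(self, pathway_id: str) -> list[str]:
        """Proper ancestors, nearest first (L3 -> [its L2, that L2's L1])."""
        out = []
        cur = self._by_id[pathway_id].parent_id
        while cur:
            out.append(cur)
            cur = self._by_id[cur].parent_id
        return out

    def subtree(self, root_id: str) -> set[str]:
        """The root plus every descendant pathway id."""
        members = {root_id}
        changed = True
        while changed:
            changed = False
            for node in self.nodes:
                if node.parent_id in members and node.pathway_id not in members:
                    members.add(node.pathway_id)
                    changed = True
        return members

    def ids_at_level(self, level: str) -> list[str]:
        return [n.pathway_id for n in self.nodes if n.level == level]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayHierarchy":
        """Columns: pathway_id, name, level, parent_id ('' for L1)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        nodes = [
            PathwayNode(r.pathway_id, r.name, r.level, r.parent_id or None)
            for r in df.itertuples(index=False)
        ]
        return cls(nodes=nodes)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(n.pathway_id, n.name, n.level, n.parent_id or "") for n in self.nodes],
            columns=["pathway_id", "name", "level", "parent_id"],
        )
        df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Direct annotations from a TSV with columns compound_id, pathway_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    direct: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        direct.setdefault(r.compound_id, set()).add(r.pathway_id)
    return direct


def write_annotations(direct: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(c, p) for c in sorted(direct) for p in sorted(direct[c])]
    pd.DataFrame(rows, columns=["compound_id", "pathway_id"]).to_csv(
        path, sep="\t", index=False
    )


def propagate_annotations(
    direct: Mapping[str, set[str]], hierarchy: PathwayHierarchy
) -> dict[str, set[str]]:
    """Upward closure of direct annotations over the hierarchy.

    ``expanded(c)`` is ``direct(c)`` plus every ancestor of its members.
    Raises :class:`HierarchyError` listing any annotation that references a
    pathway missing from the hierarchy.
    """
    unknown = sorted(
        {p for ps in direct.values() for p in ps if p not in hierarchy}
    )
    if unknown:
        raise HierarchyError(
            f"annotations reference unknown pathway ids: {', '.join(unknown)}"
        )
    expanded: dict[str, set[str]] = {}
    for compound, pathways in direct.items():
        closure = set(pathways)
        for p in pathways:
            closure.update(hierarchy.ancestors(p))
        expanded[compound] = closure
    return expanded


@dataclass(frozen=True)
class AnnotationMap:
    """Direct compound annotations plus their upward closure."""

    direct: Mapping[str, set[str]]
    expanded: Mapping[str, set[str]]

    @classmethod
    def from_direct(
        cls, direct: Mapping[str, set[str]], hierarchy: PathwayHierarchy
    ) -> "AnnotationMap":
        return cls(direct=dict(direct), expanded=propagate_annotations(direct, hierarchy))


@dataclass(frozen=True)
class PathwayFeatureVector:
    pathway_id: str
    counts: sparse.csr_matrix  # 1 x d_p
    n_positive_features: int
    size: int  # summed heavy-atom count of member compounds


def build_pathway_features(
    expanded: Mapping[str, set[str]],
    compound_ids: Sequence[str],
    compound_matrix: sparse.csr_matrix,
    compound_sizes: Mapping[str, int],
    hierarchy: PathwayHierarchy,
) -> tuple[list[str], sparse.csr_matrix, np.ndarray, np.ndarray]:
    """Aggregate member-compound features into per-pathway count vectors.

    For each pathway with at least one member compound, the feature vector
    is the element-wise sum of the members' compound vectors; pathways with
    zero members are excluded with a logged warning.  The returned matrix
    is restricted to the pathway feature vocabulary (columns positive in at
    least one pathway) -- ``kept_columns`` maps its columns back into the
    compound vocabulary.

    Returns
    -------
    (pathway_ids, pathway_matrix, pathway_sizes, kept_columns)
    """
    row_of = {c: i for i, c in enumerate(compound_ids)}
    members: dict[str, list[int]] = {n.pathway_id: [] for n in hierarchy.nodes}
    for compound, pathways in expanded.items():
        i = row_of.get(compound)
        if i is None:
            continue
        for p in pathways:
            members[p].append(i)

    kept_ids: list[str] = []
    rows: list[sparse.csr_matrix] = []
    sizes: list[int] = []
    for node in hierarchy.nodes:
        rows_idx = members[node.pathway_id]
        if not rows_idx:
            logger.warning(
                "pathway %s has no member compounds; excluded", node.pathway_id
            )
            continue
        vec = compound_matrix[rows_idx, :].sum(axis=0)
        rows.append(sparse.csr_matrix(vec, dtype=np.int64))
        kept_ids.append(node.pathway_id)
        sizes.append(sum(compound_sizes[compound_ids[i]] for i in rows_idx))
    if not rows:
        raise HierarchyError("no pathway has any member compound")
    full = sparse.vstack(rows, format="csr")
    col_sums = np.asarray(full.sum(axis=0)).ravel()
    kept_columns = np.flatnonzero(col_sums > 0)
    return kept_ids, full[:, kept_columns].tocsr(), np.asarray(sizes), kept_columns


def pathway_size(
    pathway_id: str,
    expanded: Mapping[str, set[str]],
    compound_sizes: Mapping[str, int],
) -> int:
    """Summed heavy-atom count over compounds associated with the pathway."""
    return sum(
        size
        for compound, size in compound_sizes.items()
        if pathway_id in expanded.get(compound, ())
    )
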