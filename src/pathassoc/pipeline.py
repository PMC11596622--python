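"""End-to-end dataset construction from molfiles, hierarchy, annotations.

Order of operations mirrors the dataset-construction protocol: strip
hydrogens, color atoms and build the shared vocabulary, de-duplicate
compound feature vectors, propagate annotations upward, aggregate pathway
features (and de-duplicate those), then cross-join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chemio import Molecule, strip_hydrogens
from .coloring import AUTO, ColorVocabulary, featurize_compounds
from .dataset import PairDataset, cross_join, deduplicate_entities
from .hierarchy import (
    PathwayHierarchy,
    build_pathway_features,
    propagate_annotations,
)

logger = logging.getLogger(__name__)


@dataclass
class BuildReport:
    """What the construction did: de-dup pairs and final cardinalities.

    ``n_conflicting_entries`` counts the entries whose label disagreed
    between a removed duplicate and its kept representative -- the cases
    where de-duplication silently picked one of two conflicting ground
    truths.
    """

    removed_compounds: list[tuple[str, str]] = field(default_factory=list)
    removed_pathways: list[tuple[str, str]] = field(default_factory=list)
    n_conflicting_entries: int = 0
    n_compounds: int = 0
    n_pathways: int = 0
    n_entries: int = 0
    d_compound: int = 0
    d_pathway: int = 0


def build_pair_dataset(
    molecules: Sequence[Molecule],
    hierarchy: PathwayHierarchy,
    direct_annotations: Mapping[str, set[str]],
    max_depth: int | str = 2,
    vocab: ColorVocabulary | None = None,
) -> tuple[PairDataset, BuildReport]:
    """Featurize, de-duplicate, propagate, aggregate, cross-join.

    ``max_depth`` is the coloring depth (or :data:`~pathassoc.coloring.AUTO`
    for the refinement fixpoint).  Compounds without any annotation are
    dropped (the task is defined over annotated compounds).
    """
    report = BuildReport()
    stripped = [strip_hydrogens(m) for m in molecules]
    annotated = [m for m in stripped if m.compound_id in direct_annotations]
    if len(annotated) < len(stripped):
        logger.info(
            "dropped %d compounds without annotations",
            len(stripped) - len(annotated),
        )
    ids, compound_matrix, vocab = featurize_compounds(annotated, max_depth, vocab)
    sizes = {m.compound_id: m.size for m in annotated}

    kept_ids, removed = deduplicate_entities(
        {cid: compound_matrix[i] for i, cid in enumerate(ids)}
    )
    report.removed_compounds = removed
    keep_rows = [ids.index(c) for c in kept_ids]
    compound_matrix = compound_matrix[keep_rows, :].tocsr()

    all_expanded = propagate_annotations(
        {c: ps for c, ps in direct_annotations.items() if c in set(ids)}, hierarchy
    )
    # duplicate vectors with disagreeing labels: count, then trust the kept id
    for removed_id, kept_id in removed:
        report.n_conflicting_entries += len(
            all_expanded[removed_id] ^ all_expanded[kept_id]
        )
    ids = kept_ids
    expanded = {c: all_expanded[c] for c in ids}
    pw_ids, pw_matrix, pw_sizes, _ = build_pathway_features(
        expanded, ids, compound_matrix, sizes, hierarchy
    )
    kept_pw, removed_pw = deduplicate_entities(
        {pid: pw_matrix[i] for i, pid in enumerate(pw_ids)}
    )
    report.removed_pathways = removed_pw
    for removed_id, kept_id in removed_pw:
        report.n_conflicting_entries += sum(
            (removed_id in expanded[c]) != (kept_id in expanded[c]) for c in ids
        )
    keep_pw_rows = [pw_ids.index(p) for p in kept_pw]
    pw_matrix = pw_matrix[keep_pw_rows, :].tocsr()
    pw_sizes = pw_sizes[keep_pw_rows]
    pw_ids = kept_pw

    ds = cross_join(
        compound_ids=ids,
        compound_matrix=compound_matrix,
        compound_sizes=[sizes[c] for c in ids],
        pathway_ids=pw_ids,
        pathway_matrix=pw_matrix,
        pathway_sizes=pw_sizes,
        pathway_levels=[hierarchy.level_of(p) for p in pw_ids],
        expanded=expanded,
    )
    report.n_compounds = ds.n_compounds
    report.n_pathways = ds.n_pathways
    report.n_entries = ds.n_entries
    report.d_compound = ds.d_compound
    report.d_pathway = ds.d_pathway
    return ds, report
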