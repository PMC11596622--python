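"""Synthetic fixtures: molfiles, a 3-level hierarchy, and annotations.

The generator emulates the structure of the real inputs -- compounds as
V2000 molfiles, a pathway tree with levels L1/L2/L3, and direct
compound-to-pathway annotations -- with a *planted* signal: each compound
belongs to a latent class realized as a biased element composition, and
each L3 pathway prefers one class.  ``class_purity`` controls how cleanly
a pathway's members come from its preferred class; at purity 1 with two
classes the annotation matrix is block-diagonal, while purity 0.5 with two
classes carries no signal at all (the null control).  Per-compound
in-class and off-class annotation counts are solved from
``(annotation_rate, class_purity)`` so the expected number of direct
annotations per compound equals ``annotation_rate`` while the expected
in-class share of a pathway's members equals ``class_purity``.

Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .chemio import Molecule, write_molfile
from .hierarchy import PathwayHierarchy, PathwayNode, write_annotations


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give 300 compounds against 21 pathways (3 L1 / 6 L2 / 12 L3)
    with a strong planted signal and a cross-join positive fraction of
    roughly 15% (heavily negative-dominated), matching the imbalanced
    regime of real compound-pathway data.
    """

    n_compounds: int = 300
    n_l1: int = 3
    n_l2: int = 6
    n_l3: int = 12
    size_range: tuple[int, int] = (10, 30)
    element_alphabet: tuple[str, ...] = (
        "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "Se", "B", "Si", "As"
    )
    n_classes: int = 12
    class_purity: float = 0.9
    annotation_rate: float = 1.11
    l2_annotation_rate: float = 0.1
    charge_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.class_purity <= 1.0:
            raise ValueError("class_purity must be in [0.5, 1]")
        if self.size_range[0] < 1 or self.size_range[1] < self.size_range[0]:
            raise ValueError("size_range must satisfy 1 <= min <= max")
        if min(self.n_compounds, self.n_l1, self.n_l2, self.n_l3, self.n_classes) < 1:
            raise ValueError("all counts must be positive")


def _class_element_probs(cfg: SynthConfig) -> np.ndarray:
    """Row ``z``: element distribution of class ``z``.

    Every class shares a carbon backbone (the first alphabet element) and
    carries one class-specific signature element, half-and-half.  Classes
    are therefore separable from depth-0 color counts, while the color
    space *within* a class is shared across its compounds -- a pathway's
    summed feature vector does not betray the membership of any single
    compound, mirroring real pathway features built from many members.
    """
    n_el = len(cfg.element_alphabet)
    if cfg.n_classes > n_el - 1:
        raise ValueError(
            f"element alphabet of {n_el} supports at most {n_el - 1} "
            f"classes (one is the shared backbone), got "
            f"n_classes={cfg.n_classes}"
        )
    probs = np.zeros((cfg.n_classes, n_el))
    for z in range(cfg.n_classes):
        probs[z, 0] = 0.5
        probs[z, 1 + z] = 0.5
    return probs


def generate_molecule(
    cfg: SynthConfig, class_id: int, seed: int, compound_id: str = "synthetic"
) -> tuple[Molecule, str]:
    """One random connected heavy-atom molecule plus its molfile text.

    A random tree over ``k ~ Uniform(size_range)`` atoms grown by attaching
    each new atom to a uniformly chosen atom with free valence (degree
    < 4), plus up to two extra ring-closing edges; bond orders from
    {1, 2}; element frequencies biased by the compound class.  The valence
    cap keeps the neighborhood-color space compact and shared across
    compounds, as in real organic molecules.  Byte-identical output for a
    fixed ``(cfg, class_id, seed)``.
    """
    rng = np.random.default_rng(seed)
    probs = _class_element_probs(cfg)[class_id % cfg.n_classes]
    k = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
    elements = rng.choice(cfg.element_alphabet, size=k, p=probs)
    charges = np.where(
        rng.random(k) < cfg.charge_probability, rng.choice([-1, 1], size=k), 0
    )
    degree = np.zeros(k, dtype=int)
    bonds: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for i in range(1, k):
        open_atoms = np.flatnonzero(degree[:i] < 4)
        # grow mostly chain-wise, with occasional branching
        if degree[i - 1] < 4 and rng.random() < 0.85:
            parent = i - 1
        else:
            parent = int(rng.choice(open_atoms))
        order = int(rng.choice([1, 2], p=[0.8, 0.2]))
        bonds.append((parent, i, order))
        seen.add((parent, i))
        degree[parent] += 1
        degree[i] += 1
    n_extra = int(rng.integers(0, 3))
    for _ in range(n_extra):
        if k < 3:
            break
        candidates = np.flatnonzero(degree < 4)
        if len(candidates) < 2:
            break
        a, b = sorted(rng.choice(candidates, size=2, replace=False).tolist())
        if (a, b) in seen:
            continue
        seen.add((a, b))
        bonds.append((a, b, int(rng.choice([1, 2], p=[0.8, 0.2]))))
        degree[a] += 1
        degree[b] += 1
    mol = Molecule(
        compound_id=compound_id,
        atoms=tuple((str(el), int(chg)) for el, chg in zip(elements, charges)),
        bonds=tuple(bonds),
        size=k,
    )
    return mol, write_molfile(mol)


def generate_hierarchy(cfg: SynthConfig, seed: int | None = None) -> PathwayHierarchy:
    """Balanced 3-level tree: parents assigned round-robin.

    ``L2_i`` sits under ``L1_{i mod n_l1}`` and ``L3_i`` under
    ``L2_{i mod n_l2}``.  The balanced assignment keeps every pathway's
    structural popularity comparable, so under entry-level splitting no
    pathway carries a predictable base-rate advantage that is unrelated to
    the planted class signal.
    """
    del seed  # the balanced tree is deterministic
    nodes = [
        PathwayNode(f"L1_{i:03d}", f"Top category {i}", "L1", None)
        for i in range(cfg.n_l1)
    ]
    for i in range(cfg.n_l2):
        parent = f"L1_{i % cfg.n_l1:03d}"
        nodes.append(PathwayNode(f"L2_{i:03d}", f"Subcategory {i}", "L2", parent))
    for i in range(cfg.n_l3):
        parent = f"L2_{i % cfg.n_l2:03d}"
        nodes.append(PathwayNode(f"L3_{i:03d}", f"Pathway {i}", "L3", parent))
    return PathwayHierarchy(nodes=nodes)


def pathway_preferred_classes(cfg: SynthConfig) -> dict[str, int]:
    """L3 pathway -> preferred latent class (round-robin assignment)."""
    return {f"L3_{i:03d}": i % cfg.n_classes for i in range(cfg.n_l3)}


def annotation_counts(cfg: SynthConfig) -> tuple[float, float]:
    """Expected per-compound annotation counts (in-class, off-class).

    A compound draws ``i = annotation_rate * class_purity`` annotations
    among the L3 pathways preferring its class and ``o = annotation_rate *
    (1 - class_purity)`` among the rest, so the expected in-class share of
    a pathway's members is exactly ``class_purity`` and the expected number
    of direct annotations per compound is ``annotation_rate``.  At purity
    0.5 with two classes the two draws are symmetric: no class signal.
    """
    return (
        cfg.annotation_rate * cfg.class_purity,
        cfg.annotation_rate * (1.0 - cfg.class_purity),
    )


def _stochastic_round(value: float, rng: np.random.Generator) -> int:
    base = int(np.floor(value))
    return base + int(rng.random() < (value - base))


def generate_annotations(
    cfg: SynthConfig,
    hierarchy: PathwayHierarchy,
    compound_classes: Mapping[str, int],
    seed: int | None = None,
) -> dict[str, set[str]]:
    """Direct annotations with the planted class signal.

    Per compound, a near-constant number of draws (stochastically rounded
    ``i`` in-class and ``o`` off-class, see :func:`annotation_counts`)
    sampled uniformly without replacement -- keeping each compound's
    annotation propensity comparable, so the only exploitable structure is
    the class signal itself.  Mostly to L3 pathways; occasionally
    (``l2_annotation_rate``) a direct L2 annotation is added, mimicking
    real annotations that skip the individual-pathway level.  Every
    compound has at least one direct annotation (the real inputs only
    include annotated compounds).
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    prefs = pathway_preferred_classes(cfg)
    l3_ids = list(prefs)
    exp_in, exp_out = annotation_counts(cfg)
    top_of = {p: hierarchy.ancestors(p)[-1] for p in l3_ids}
    direct: dict[str, set[str]] = {}
    for compound_id in compound_classes:
        z = compound_classes[compound_id]
        in_class = [p for p in l3_ids if prefs[p] == z] or l3_ids
        off_all = [p for p in l3_ids if prefs[p] != z]
        n_in = max(1, min(len(in_class), _stochastic_round(exp_in, rng)))
        chosen = set(
            rng.choice(in_class, size=n_in, replace=False).tolist()
        )
        # off-class noise prefers pathways related to the drawn ones:
        # siblings first, then pathways under the same top category --
        # mis-annotations land in nearby pathways, and the noise perturbs
        # each compound's propagated label count as little as possible.
        siblings = [
            p
            for p in off_all
            if any(
                hierarchy.parent_of(p) == hierarchy.parent_of(q)
                for q in chosen
            )
        ]
        own_tops = {top_of[q] for q in chosen}
        near = [p for p in off_all if top_of[p] in own_tops]
        off_class = siblings or near or off_all
        n_out = min(len(off_class), _stochastic_round(exp_out, rng))
        if n_out:
            chosen.update(rng.choice(off_class, size=n_out, replace=False).tolist())
        if rng.random() < cfg.l2_annotation_rate:
            # a direct L2 annotation, as real data sometimes skips the
            # individual-pathway level; drawn over an annotated pathway so
            # it is consistent with the compound's L3 annotations
            drawn = sorted(chosen)
            p = drawn[int(rng.integers(0, len(drawn)))]
            parent = hierarchy.parent_of(p)
            if parent:
                chosen.add(parent)
        direct[compound_id] = chosen
    return direct


@dataclass
class SyntheticData:
    """A complete generated study: molecules, hierarchy, annotations."""

    config: SynthConfig
    molecules: list[Molecule]
    molfiles: dict[str, str]
    hierarchy: PathwayHierarchy
    direct_annotations: dict[str, set[str]]
    compound_classes: dict[str, int] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """molfiles/*.mol, hierarchy.tsv, annotations.tsv, manifest.json."""
        out = Path(out_dir)
        (out / "molfiles").mkdir(parents=True, exist_ok=True)
        for cid, text in self.molfiles.items():
            (out / "molfiles" / f"{cid}.mol").write_text(text)
        self.hierarchy.to_tsv(out / "hierarchy.tsv")
        write_annotations(self.direct_annotations, out / "annotations.tsv")
        manifest = {
            "config": asdict(self.config),
            "n_molecules": len(self.molecules),
            "compound_classes": self.compound_classes,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate(cfg: SynthConfig | None = None) -> SyntheticData:
    """Generate a full synthetic study from one seed."""
    cfg = cfg or SynthConfig()
    classes = {
        f"syn{i:05d}": i % cfg.n_classes for i in range(cfg.n_compounds)
    }
    molecules = []
    molfiles = {}
    for i, (cid, z) in enumerate(classes.items()):
        mol, text = generate_molecule(cfg, z, seed=cfg.seed * 1_000_003 + i, compound_id=cid)
        molecules.append(mol)
        molfiles[cid] = text
    hierarchy = generate_hierarchy(cfg)
    direct = generate_annotations(cfg, hierarchy, classes)
    return SyntheticData(
        config=cfg,
        molecules=molecules,
        molfiles=molfiles,
        hierarchy=hierarchy,
        direct_annotations=direct,
        compound_classes=classes,
    )
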