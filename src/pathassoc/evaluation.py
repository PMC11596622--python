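"""Confusion-matrix accumulation, metrics, and the CV analysis.

The evaluation protocol: repeated stratified train/test cross-validation
over the entry-level pair dataset.  Each iteration's test predictions are
tallied into an overall confusion matrix; in parallel, every test entry's
outcome is credited to its compound and to its pathway, and those
per-entity counts are summed *across* iterations so that rarely-positive
entities still accumulate a defined confusion matrix.  Metrics over a
scope are always derived from its summed counts.

The Matthews correlation coefficient (MCC) is computed with an exact
integer numerator and a log-space square root of the marginal product, so
counts in the tens of millions (where the naive product overflows 64-bit
integers) lose no precision.  A metric whose defining denominator is zero
is UNDEFINED and reported as ``None`` -- never coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PairDataset, stratified_split
from .hierarchy import PathwayHierarchy
from .model import AssociationMLP, MLPConfig


@dataclass(frozen=True)
class ConfusionCounts:
    """A 2x2 tally of binary predictions."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """The six derived metrics; ``None`` marks an UNDEFINED value."""

    mcc: float | None
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    specificity: float | None


def confusion(
    true_labels: Sequence[int] | np.ndarray, predicted_labels: Sequence[int] | np.ndarray
) -> ConfusionCounts:
    """Standard 2x2 tally; raises on length mismatch."""
    y = np.asarray(true_labels).astype(bool)
    p = np.asarray(predicted_labels).astype(bool)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum(y & p)),
        tn=int(np.sum(~y & ~p)),
        fp=int(np.sum(~y & p)),
        fn=int(np.sum(y & ~p)),
    )


def mcc(c: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient, or ``None`` when undefined.

    ``(tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))`` with the
    numerator in exact integer arithmetic and the denominator as
    ``exp(0.5 * sum(log(factor)))``; ``None`` when any marginal is zero.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    factors = (tp + fp, tp + fn, tn + fp, tn + fn)
    if any(f == 0 for f in factors):
        return None
    num = tp * tn - fp * fn  # exact Python int
    if num == 0:
        return 0.0
    log_den = 0.5 * sum(math.log(f) for f in factors)
    return math.copysign(math.exp(math.log(abs(num)) - log_den), num)


def derived_metrics(c: ConfusionCounts) -> MetricSet:
    """All six metrics from one confusion matrix; zero denominators -> None."""
    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return MetricSet(
        mcc=mcc(c),
        accuracy=ratio(c.tp + c.tn, c.total),
        precision=ratio(c.tp, c.tp + c.fp),
        recall=ratio(c.tp, c.tp + c.fn),
        f1=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
    )


@dataclass
class CVResult:
    """Outcome of a repeated stratified CV analysis.

    ``per_iteration_overall[i]`` is iteration ``i``'s overall test-set
    confusion matrix.  ``per_compound`` / ``per_pathway`` hold per-entity
    counts summed across all iterations.  For every iteration the
    per-pathway (and per-compound) counts of that iteration partition the
    overall counts, so the grand sums agree.
    """

    per_iteration_overall: list[ConfusionCounts]
    per_compound: dict[str, ConfusionCounts]
    per_pathway: dict[str, ConfusionCounts]
    seeds: list[int]
    pathway_levels: dict[str, str] = field(default_factory=dict)
    compound_sizes: dict[str, int] = field(default_factory=dict)
    pathway_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration_overall)

    def pooled_overall(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.per_iteration_overall:
            total = total + c
        return total

    def summary(self) -> str:
        mean, median, std = aggregate_overall(self, "mcc")
        lines = [
            f"Cross-validation analysis ({self.n_iterations} iterations)",
            f"  MCC across iterations: mean {mean:.3f}, median {median:.3f}, "
            f"std {std:.4f}",
            "  MCC by pathway hierarchy level (summed counts):",
        ]
        for level, m in aggregate_by_group(self, "level").items():
            shown = "undefined" if m.mcc is None else f"{m.mcc:.3f}"
            lines.append(f"    {level}: {shown}")
        return "\n".join(lines)


def run_cv(
    ds: PairDataset,
    cfg: MLPConfig,
    n_iterations: int,
    base_seed: int = 0,
    test_fraction: float = 0.1,
) -> CVResult:
    """Repeated stratified CV with per-entity confusion accumulation.

    Iteration ``i`` uses seed ``base_seed + i`` for both the split and the
    model; identical arguments reproduce an identical result.  Training
    errors abort with the iteration index attached.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n_c, n_p = ds.n_compounds, ds.n_pathways
    per_compound = np.zeros((n_c, 4), dtype=np.int64)  # tp, tn, fp, fn
    per_pathway = np.zeros((n_p, 4), dtype=np.int64)
    overall: list[ConfusionCounts] = []
    seeds: list[int] = []

    for i in range(n_iterations):
        seed = base_seed + i
        seeds.append(seed)
        plan = stratified_split(ds, test_fraction, seed, iteration=i)
        model = AssociationMLP(ds, MLPConfig(**{**cfg.__dict__, "seed": seed})).fit(plan)
        try:
            _, pred = model.predict(ds, plan.test_indices)
        except Exception as exc:  # pragma: no cover - propagated diagnostics
            raise RuntimeError(f"prediction failed in CV iteration {i}") from exc
        y = ds.entry_labels(plan.test_indices).astype(bool)
        p = pred.astype(bool)
        i_c, i_p = ds.entry_pairs(plan.test_indices)
        outcome = np.select(
            [y & p, ~y & ~p, ~y & p], [0, 1, 2], default=3
        )  # columns: tp, tn, fp, fn
        for col in range(4):
            mask = outcome == col
            per_compound[:, col] += np.bincount(i_c[mask], minlength=n_c)
            per_pathway[:, col] += np.bincount(i_p[mask], minlength=n_p)
        overall.append(confusion(y, p))

    def to_map(ids: Sequence[str], arr: np.ndarray) -> dict[str, ConfusionCounts]:
        return {
            ids[i]: ConfusionCounts(*map(int, arr[i])) for i in range(len(ids))
        }

    return CVResult(
        per_iteration_overall=overall,
        per_compound=to_map(ds.compound_ids, per_compound),
        per_pathway=to_map(ds.pathway_ids, per_pathway),
        seeds=seeds,
        pathway_levels=dict(zip(ds.pathway_ids, ds.pathway_levels)),
        compound_sizes=dict(zip(ds.compound_ids, map(int, ds.compound_sizes))),
        pathway_sizes=dict(zip(ds.pathway_ids, map(int, ds.pathway_sizes))),
    )


_METRIC_NAMES = ("mcc", "accuracy", "precision", "recall", "f1", "specificity")


def aggregate_overall(
    cv: CVResult, metric: str = "mcc"
) -> tuple[float, float, float]:
    """Mean, median and sample std of a metric across CV iterations.

    Iterations where the metric is UNDEFINED are skipped; raises if every
    iteration is undefined.
    """
    if metric not in _METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    values = [
        v
        for c in cv.per_iteration_overall
        if (v := getattr(derived_metrics(c), metric)) is not None
    ]
    if not values:
        raise ValueError(f"metric {metric!r} is undefined in every iteration")
    arr = np.asarray(values)
    std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), float(np.median(arr)), std


Grouping = Literal["level", "l1_subtree", "pathway", "compound"]


def aggregate_by_group(
    cv: CVResult,
    grouping: Grouping,
    hierarchy: PathwayHierarchy | None = None,
) -> dict[str, MetricSet]:
    """Metrics from counts summed within each group.

    ``level``      -- pathways grouped by hierarchy level (L1/L2/L3).
    ``l1_subtree`` -- every pathway under each L1, including the L1 itself
                      (requires ``hierarchy``).
    ``pathway`` / ``compound`` -- each entity by itself.

    UNDEFINED metrics propagate as ``None``.
    """
    if grouping == "pathway":
        return {p: derived_metrics(c) for p, c in cv.per_pathway.items()}
    if grouping == "compound":
        return {c: derived_metrics(k) for c, k in cv.per_compound.items()}
    if grouping == "level":
        groups: dict[str, ConfusionCounts] = {}
        for p, counts in cv.per_pathway.items():
            level = cv.pathway_levels[p]
            groups[level] = groups.get(level, ConfusionCounts()) + counts
        return {
            lvl: derived_metrics(groups[lvl]) for lvl in ("L1", "L2", "L3") if lvl in groups
        }
    if grouping == "l1_subtree":
        if hierarchy is None:
            raise ValueError("l1_subtree grouping requires the pathway hierarchy")
        out: dict[str, MetricSet] = {}
        for l1 in hierarchy.ids_at_level("L1"):
            members = hierarchy.subtree(l1)
            total = ConfusionCounts()
            seen = False
            for p in members:
                if p in cv.per_pathway:
                    total = total + cv.per_pathway[p]
                    seen = True
            if seen:
                out[l1] = derived_metrics(total)
        return out
    raise ValueError(f"unknown grouping {grouping!r}")


def size_mcc_correlation(
    sizes: Mapping[str, int], mccs: Mapping[str, float | None]
) -> tuple[float, float]:
    """Pearson r (with two-sided t-test p-value) between size and MCC.

    Entities with an UNDEFINED MCC are excluded.  Raises on fewer than 3
    usable pairs or zero variance on either axis.
    """
    pairs = [
        (sizes[k], v) for k, v in mccs.items() if v is not None and k in sizes
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired defined values, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in sizes or MCCs")
    r, p_value = stats.pearsonr(x, y)
    return float(r), float(p_value)


# ---------------------------------------------------------------------------
# Report export


def _metrics_row(m: MetricSet) -> dict:
    return {
        name: (None if getattr(m, name) is None else round(getattr(m, name), 3))
        for name in _METRIC_NAMES
    }


def write_reports(
    cv: CVResult,
    out_dir: str | Path,
    hierarchy: PathwayHierarchy | None = None,
) -> None:
    """TSV/JSON reports: per-iteration, per-level, per-subtree, per-entity.

    Metrics are rounded to 3 decimal places in the TSVs; the JSON keeps
    full precision.  UNDEFINED metrics appear as empty TSV cells / JSON
    nulls.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, c in enumerate(cv.per_iteration_overall):
        rows.append(
            {"iteration": i, "seed": cv.seeds[i], **_metrics_row(derived_metrics(c)),
             "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
        )
    pd.DataFrame(rows).to_csv(out / "overall_iterations.tsv", sep="\t", index=False)

    mean, median, std = aggregate_overall(cv, "mcc")
    level_rows = [
        {"level": lvl, **_metrics_row(m)}
        for lvl, m in aggregate_by_group(cv, "level").items()
    ]
    pd.DataFrame(level_rows).to_csv(out / "level_metrics.tsv", sep="\t", index=False)

    if hierarchy is not None:
        sub_rows = [
            {"l1_pathway": l1, **_metrics_row(m)}
            for l1, m in aggregate_by_group(cv, "l1_subtree", hierarchy).items()
        ]
        pd.DataFrame(sub_rows).to_csv(out / "l1_subtree_metrics.tsv", sep="\t", index=False)

    for name, per_entity in (("pathway", cv.per_pathway), ("compound", cv.per_compound)):
        ent_rows = [
            {"id": k, "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
             **_metrics_row(derived_metrics(c))}
            for k, c in per_entity.items()
        ]
        pd.DataFrame(ent_rows).to_csv(out / f"per_{name}_counts.tsv", sep="\t", index=False)

    full = {
        "n_iterations": cv.n_iterations,
        "seeds": cv.seeds,
        "mcc_mean": mean,
        "mcc_median": median,
        "mcc_std": std,
        "per_iteration": [
            {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
             "mcc": derived_metrics(c).mcc}
            for c in cv.per_iteration_overall
        ],
    }
    (out / "cv_summary.json").write_text(json.dumps(full, indent=2))
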