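"""The four phases of hierarchical feature engineering.

Starting from ``m`` OTU features, the feature space is first *grown* by
aggregation: every named taxon becomes a candidate feature whose relative
abundance is the sum of its children's, giving ``m + m'`` candidates for a
tree with ``m'`` internal nodes.  Three filters then shrink it:

1. **Correlation filter** — a child (internal taxon or OTU) whose Pearson
   correlation with its immediate parent exceeds a threshold ``theta`` is
   redundant and discarded (``s1`` features).
2. **Information-gain path filter** — each OTU lineage defines a
   root-to-leaf path; along each path the mean information gain (after
   supervised MDL discretization) sets a threshold, and a node survives if
   it reaches the threshold with positive gain on at least one path
   through it (``s2`` discarded).  Leaves of incomplete paths are deferred.
3. **Leaf filter** — OTUs attached above species level are kept only when
   their gain is positive and at least the global mean gain of the phase-3
   survivors (``s3`` discarded).

The final feature space has ``m + m' - s1 - s2 - s3`` features.  All
statistics (correlations, discretizations, gains) are computed on the
samples passed in, which in cross-validation are the training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import DiscretizationScheme, information_gain, mdlp_discretize
from .io import AbundanceTable, LabelVector
from .taxonomy import TaxonomyTree

__all__ = [
    "HFEResult",
    "aggregate_taxa",
    "correlation_filter",
    "ig_path_filter",
    "ig_leaf_filter",
    "run_hfe",
]


@dataclass
class HFEResult:
    """Outcome of a feature-engineering run on one training set."""

    selected: tuple[str, ...]
    ig_scores: dict[str, float]
    s1: int
    s2: int
    s3: int
    theta: float
    m: int
    m_prime: int
    global_avg_ig: float = 0.0
    phase3_average: str = "per-path"
    discarded: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.selected) != self.m + self.m_prime - self.s1 - self.s2 - self.s3:
            raise AssertionError(
                "feature count identity violated: "
                f"{len(self.selected)} != {self.m} + {self.m_prime} - "
                f"{self.s1} - {self.s2} - {self.s3}"
            )


def aggregate_taxa(table: AbundanceTable, tree: TaxonomyTree) -> AbundanceTable:
    """Phase 1: extend the OTU table with one aggregate column per named taxon.

    Internal-node columns are computed bottom-up, each parent summing its
    already-aggregated children, so every taxon column equals the sum of
    its OTU descendants.  OTU columns pass through unchanged; the output
    has ``m + m'`` features (super-root excluded).
    """
    missing = [f for f in table.feature_ids if f not in tree.otu_attachment]
    if missing:
        raise ValueError(f"table features absent from tree: {missing[:5]}")
    vals = table.values()
    col = {otu: i for i, otu in enumerate(table.feature_ids)}
    agg: dict[str, np.ndarray] = {}
    # deepest-first so children are ready before their parent
    order = sorted(
        tree.nodes.values(), key=lambda nd: (-int(nd.rank), nd.id)  # type: ignore[arg-type]
    )
    for node in order:
        total = np.zeros(table.n_samples)
        for otu in node.otus:
            total += vals[:, col[otu]]
        for child in node.children:
            total += agg[child.id]
        agg[node.id] = total
    internal_ids = tree.internal_ids
    out = pd.DataFrame(
        np.column_stack([vals] + [agg[i] for i in internal_ids]),
        index=table.data.index,
        columns=list(table.feature_ids) + internal_ids,
    )
    return AbundanceTable(out, normalized=table.normalized)


def _pearson_edges(
    extended: AbundanceTable, edges: list[tuple[str, str]]
) -> np.ndarray:
    """Pearson correlation per (parent, child) feature pair; 0 where undefined."""
    vals = extended.values()
    centered = vals - vals.mean(axis=0)
    sd = centered.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, centered / sd, 0.0)
    col = {f: i for i, f in enumerate(extended.feature_ids)}
    pi = np.array([col[p] for p, _ in edges])
    ci = np.array([col[c] for _, c in edges])
    n = vals.shape[0]
    return np.einsum("ij,ij->j", z[:, pi], z[:, ci]) / n


def correlation_filter(
    extended: AbundanceTable, tree: TaxonomyTree, theta: float = 0.7
) -> tuple[list[str], int]:
    """Phase 2: discard children redundant with their immediate parent.

    For every parent-child edge of the hierarchy (child = internal taxon or
    OTU leaf) the Pearson correlation between the two feature columns is
    computed over all samples; the child is discarded iff rho > theta
    (strictly).  Undefined correlations (a zero-variance column) count as
    0, keeping the child.  Kingdom-level nodes have no parent feature and
    are never discarded here.

    Returns the retained feature ids (in extended-table column order) and
    the discard count ``s1``.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    edge_list = [(parent.id, child) for parent, child in tree.edges()]
    rho = _pearson_edges(extended, edge_list) if edge_list else np.empty(0)
    discarded = {child for (_, child), r in zip(edge_list, rho) if r > theta}
    retained = [f for f in extended.feature_ids if f not in discarded]
    return retained, len(discarded)


def _ig_cache(
    features: list[str], extended: AbundanceTable, y: np.ndarray
) -> dict[str, float]:
    vals = extended.values()
    col = {f: i for i, f in enumerate(extended.feature_ids)}
    out: dict[str, float] = {}
    for f in features:
        v = vals[:, col[f]]
        scheme = mdlp_discretize(v, y)
        out[f] = information_gain(scheme, v, y)
    return out


def ig_path_filter(
    retained: list[str],
    extended: AbundanceTable,
    tree: TaxonomyTree,
    labels: LabelVector,
    *,
    average: str = "per-path",
    ig: dict[str, float] | None = None,
) -> tuple[list[str], int, float]:
    """Phase 3: keep the informative nodes of each lineage path.

    Every OTU's lineage is walked root-to-leaf; on each path the mean IG of
    the phase-2-retained nodes is the threshold, and a node survives if on
    at least one of its paths IG >= mean with IG > 0.  With
    ``average="global"`` a single mean over all candidates replaces the
    per-path thresholds.  Leaves of incomplete paths are exempt — they are
    neither filtered nor counted in path means — and pass through to
    phase 4.

    Returns (kept features, ``s2``, global mean IG of the kept nodes).
    """
    if average not in ("per-path", "global"):
        raise ValueError(f"unknown phase-3 averaging mode: {average!r}")
    retained_set = set(retained)
    exempt = tree.incomplete_leaves() & retained_set
    candidates = [f for f in retained if f not in exempt]
    y = labels.for_samples(extended.sample_ids)
    if ig is None:
        ig = _ig_cache(candidates, extended, y)
    keep: set[str] = set()
    if average == "global":
        vals = [ig[f] for f in candidates]
        thr = float(np.mean(vals)) if vals else 0.0
        keep = {f for f in candidates if ig[f] > 0 and ig[f] >= thr}
    else:
        for otu in tree.otu_ids:
            path = tree.lineage_path(otu)
            if tree.otu_lineages[otu].complete:
                path = path + [otu]
            nodes = [f for f in path if f in retained_set and f not in exempt]
            if not nodes:
                continue
            thr = float(np.mean([ig[f] for f in nodes]))
            keep.update(f for f in nodes if ig[f] > 0 and ig[f] >= thr)
    kept = [f for f in candidates if f in keep]
    s2 = len(candidates) - len(kept)
    global_avg = float(np.mean([ig[f] for f in kept])) if kept else 0.0
    return kept, s2, global_avg


def ig_leaf_filter(
    incomplete_retained: list[str],
    extended: AbundanceTable,
    labels: LabelVector,
    global_avg_ig: float,
    *,
    ig: dict[str, float] | None = None,
) -> tuple[list[str], int]:
    """Phase 4: filter the leaves of incomplete paths.

    An OTU attached above species level survives iff its IG is positive and
    at least the global mean IG of the phase-3 survivors.  No cap on the
    fraction discarded.  Returns (kept leaves, ``s3``).
    """
    y = labels.for_samples(extended.sample_ids)
    if ig is None:
        ig = _ig_cache(incomplete_retained, extended, y)
    kept = [f for f in incomplete_retained if ig[f] > 0 and ig[f] >= global_avg_ig]
    return kept, len(incomplete_retained) - len(kept)


def run_hfe(
    table: AbundanceTable,
    labels: LabelVector,
    tree: TaxonomyTree,
    theta: float = 0.7,
    *,
    phase3_average: str = "per-path",
    _extended: AbundanceTable | None = None,
) -> HFEResult:
    """Run phases 1-4 on one (training) sample set.

    ``table`` must be normalized per sample and cover exactly the tree's
    OTUs; ``labels`` must cover its samples.  Deterministic for fixed
    inputs.  ``_extended`` optionally supplies a precomputed phase-1 table
    (rows must match ``table``'s samples) so repeated calls, e.g. across
    folds, skip re-aggregation.
    """
    if not table.normalized:
        raise ValueError("run_hfe expects a per-sample normalized table")
    extended = _extended if _extended is not None else aggregate_taxa(table, tree)
    retained, s1 = correlation_filter(extended, tree, theta)
    y = labels.for_samples(extended.sample_ids)
    ig = _ig_cache(retained, extended, y)
    kept3, s2, global_avg = ig_path_filter(
        retained, extended, tree, labels, average=phase3_average, ig=ig
    )
    incomplete_retained = [f for f in retained if f in tree.incomplete_leaves()]
    kept4, s3 = ig_leaf_filter(
        incomplete_retained, extended, labels, global_avg, ig=ig
    )
    keep_set = set(kept3) | set(kept4)
    selected = tuple(f for f in extended.feature_ids if f in keep_set)
    return HFEResult(
        selected=selected,
        ig_scores={f: ig[f] for f in selected},
        s1=s1,
        s2=s2,
        s3=s3,
        theta=theta,
        m=tree.m,
        m_prime=tree.m_prime,
        global_avg_ig=global_avg,
        phase3_average=phase3_average,
        discarded={},
    )
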