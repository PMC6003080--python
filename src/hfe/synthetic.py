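"""Synthetic taxonomies and case/control abundance tables with planted clades.

The generator emulates the structure 16S rRNA case-control studies hand to
the pipeline: a multi-rank taxonomy with a configurable share of OTUs whose
classification stops at family or genus level, long-tailed compositional
abundance profiles, and a class effect that is *oligophyletic* — applied to
every OTU descending from one chosen internal taxon, so that the ancestral
taxon is a better feature than any single member OTU.

Abundance model: per-OTU base proportions are drawn log-normally (a few
taxa dominate, most are rare).  Per sample, every species- and genus-level
taxon receives a shared log-normal factor that multiplies all of its
member OTUs — the within-clade covariation that makes ancestral taxa
coherent features in real 16S data — plus independent per-OTU log-normal
noise; ``noise`` scales the log-sd of all of these factors.  The factor
scale decays sharply with rank (strong within species, weak within genus,
none broader): ecological fluctuation is nearly clonal among same-species
OTUs, while a whole family rarely blooms as a unit.  In case samples the
planted clade's abundances are multiplied by ``effect_size`` *before* the
per-sample renormalization, so all other features shift slightly too —
the realistic compositional confound.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable, LabelVector
from .taxonomy import (
    NAMED_RANKS,
    Lineage,
    Rank,
    RANK_PREFIXES,
    TaxonomyTree,
    build_tree,
)

__all__ = [
    "SyntheticTruth",
    "random_taxonomy",
    "generate_dataset",
    "simulate",
    "choose_planted_node",
    "recovery_neighborhood",
]

GENERATOR_VERSION = "1.0"

#: Per-rank mean child counts for the generated hierarchy.  The profile is
#: wide at the genus level: observed 16S families typically contribute
#: several genera, and that width is what keeps a genus from being
#: numerically identical to its family — the regime taxon aggregation
#: targets.  Every family receives at least two genera.
BRANCHING = {
    Rank.PHYLUM: 3.0,
    Rank.CLASS: 2.0,
    Rank.ORDER: 2.0,
    Rank.FAMILY: 2.5,
    Rank.GENUS: 3.5,
    Rank.SPECIES: 2.5,
}

#: Shared-lineage factor scale per rank (multiplied by ``noise``).
#: Covariation decays with taxonomic distance: OTUs of one species are
#: ecologically near-clonal and fluctuate together; genus-wide coherent
#: shifts are much weaker; broader ranks are not modelled.
FACTOR_WEIGHTS = {
    Rank.GENUS: 0.25,
    Rank.SPECIES: 1.5,
}

#: Study-condition defaults: cohort and table sizes typical of a single
#: 16S case-control study, genus-level effect, moderate overdispersion.
DEFAULTS = dict(
    n_otus=200,
    n_samples=100,
    incomplete_fraction=0.1,
    effect_rank=Rank.GENUS,
    effect_size=3.0,
    noise=0.5,
    base_sigma=1.5,
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a planted case/control effect."""

    planted_node: str
    effect_rank: Rank
    effect_size: float
    incomplete_fraction: float
    n_samples: int
    n_otus: int
    seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_rank"] = self.effect_rank.name.lower()
        d["generator_version"] = GENERATOR_VERSION
        return d


def _branching_profile(
    branching: float | dict[Rank, float] | None,
) -> dict[Rank, float]:
    if branching is None:
        return dict(BRANCHING)
    if isinstance(branching, dict):
        profile = dict(BRANCHING)
        profile.update(branching)
        return profile
    return {r: float(branching) for r in BRANCHING}


def random_taxonomy(
    n_otus: int,
    branching: float | dict[Rank, float] | None = None,
    incomplete_fraction: float = DEFAULTS["incomplete_fraction"],
    seed: int = 0,
) -> TaxonomyTree:
    """Generate a random 7-rank taxonomy and attach ``n_otus`` OTUs.

    The named hierarchy grows top-down from a single kingdom; each node's
    child count is drawn with the per-rank mean given by ``branching`` (a
    scalar applies to all ranks; default :data:`BRANCHING`), with at least
    two genera per family.  OTUs are assigned to species uniformly at
    random.  A fraction of OTUs get lineages truncated at family or genus
    level (drawn uniformly), mirroring the partial classifications real
    reference databases yield.
    """
    if n_otus < 1:
        raise ValueError("n_otus must be >= 1")
    if not 0.0 <= incomplete_fraction < 1.0:
        raise ValueError("incomplete_fraction must be in [0, 1)")
    profile = _branching_profile(branching)
    if any(b < 1.0 for b in profile.values()):
        raise ValueError("branching means must be >= 1")
    rng = np.random.default_rng(seed)
    counters = {r: 0 for r in NAMED_RANKS}

    def expand(names: tuple[str, ...], depth: int, out: list[tuple[str, ...]]) -> None:
        if depth == len(NAMED_RANKS):
            out.append(names)
            return
        rank = NAMED_RANKS[depth]
        mean = profile[rank]
        floor = 2 if rank is Rank.GENUS and mean >= 2.0 else 1
        n_children = floor + int(rng.poisson(max(mean - floor, 0.0)))
        for _ in range(n_children):
            counters[rank] += 1
            expand(names + (f"{RANK_PREFIXES[rank]}{counters[rank]}",), depth + 1, out)

    species_paths: list[tuple[str, ...]] = []
    expand(("Bacteria",), 1, species_paths)
    assignment = rng.integers(0, len(species_paths), size=n_otus)
    otu_ids = [f"{100001 + i}" for i in range(n_otus)]
    n_trunc = int(round(incomplete_fraction * n_otus))
    truncated = set(rng.choice(n_otus, size=n_trunc, replace=False).tolist())
    lineages: dict[str, Lineage] = {}
    for i, otu in enumerate(otu_ids):
        names = species_paths[assignment[i]]
        if i in truncated:
            depth = int(rng.choice([Rank.FAMILY, Rank.GENUS])) + 1
            names = names[:depth]
        lineages[otu] = Lineage(names)
    return build_tree(otu_ids, lineages)


def _base_proportions(
    m: int, seed: int, base_sigma: float
) -> tuple[np.ndarray, np.random.Generator]:
    """Deterministic long-tailed base composition; returns the live stream too.

    Both :func:`simulate` (to judge clade dominance when planting) and
    :func:`generate_dataset` (to build the table) must see the identical
    base vector, so the draw is pinned to the head of the ``[seed, 7]``
    stream.
    """
    rng = np.random.default_rng([seed, 7])
    base = rng.lognormal(mean=0.0, sigma=base_sigma, size=m)
    return base / base.sum(), rng


def _otu_descendants(tree: TaxonomyTree, node_id: str) -> list[str]:
    node = tree.nodes[node_id]
    out: list[str] = []
    stack = [node]
    while stack:
        nd = stack.pop()
        out.extend(nd.otus)
        stack.extend(nd.children)
    return sorted(out)


def choose_planted_node(
    tree: TaxonomyTree,
    rank: Rank,
    rng: np.random.Generator,
    min_otus: int = 4,
    abundance: dict[str, float] | None = None,
    max_parent_share: float = 0.4,
) -> str:
    """Pick a taxon at ``rank`` to carry the planted trait.

    The taxon must have at least ``min_otus`` descendant OTUs — the
    oligophyletic setting where an ancestral taxon genuinely carries more
    signal than any single member.  When per-OTU base ``abundance`` is
    given, the taxon must also be a minority constituent of its parent
    (clade abundance at most ``max_parent_share`` of the parent's): a
    taxon that already dominates its parent is numerically interchangeable
    with it and does not probe taxonomic abstraction.  Falls back to the
    least-dominant, then the largest, clade when no taxon qualifies.
    """
    sized = sorted(
        (nid, len(_otu_descendants(tree, nid)))
        for nid, node in tree.nodes.items()
        if node.rank == rank
    )
    if not sized:
        raise ValueError(f"tree has no {rank.name.lower()}-level taxa")
    big_enough = [nid for nid, k in sized if k >= min_otus]
    if not big_enough:
        biggest = max(k for _, k in sized)
        return str(rng.choice([nid for nid, k in sized if k == biggest]))
    if abundance is None:
        return str(rng.choice(big_enough))
    shares: dict[str, float] = {}
    for nid in big_enough:
        parent = tree.nodes[nid].parent
        own = sum(abundance[o] for o in _otu_descendants(tree, nid))
        if parent is None or parent.is_root:
            shares[nid] = 1.0
            continue
        total = sum(abundance[o] for o in _otu_descendants(tree, parent.id))
        shares[nid] = own / total if total > 0 else 1.0
    minority = sorted(nid for nid in big_enough if shares[nid] <= max_parent_share)
    if minority:
        return str(rng.choice(minority))
    return min(big_enough, key=lambda nid: (shares[nid], nid))


def generate_dataset(
    tree: TaxonomyTree,
    truth: SyntheticTruth,
    noise: float = DEFAULTS["noise"],
    base_sigma: float = DEFAULTS["base_sigma"],
) -> tuple[AbundanceTable, LabelVector, SyntheticTruth]:
    """Draw a balanced case/control table of relative abundances.

    ``noise`` scales every stochastic per-sample factor: the shared
    log-normal factor per family/genus/species taxon and the independent
    per-OTU log-normal noise all have log-sd ``noise``.  ``noise=0``
    yields noise-free compositions equal to the class means, so the
    planted aggregate separates the classes perfectly.  Rows are
    renormalized to 1, so the table arrives already compositional.
    """
    if truth.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if truth.effect_size < 1.0:
        raise ValueError("effect_size must be >= 1")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    otu_ids = tree.otu_ids
    m = len(otu_ids)
    base, rng = _base_proportions(m, truth.seed, base_sigma)
    clade = set(_otu_descendants(tree, truth.planted_node))
    in_clade = np.array([o in clade for o in otu_ids])
    n = truth.n_samples
    n_case = n // 2
    labels_arr = np.array(["control"] * (n - n_case) + ["case"] * n_case, dtype=object)
    # map each OTU to its shared-lineage factor columns
    factor_nodes = [
        nid
        for nid, nd in tree.nodes.items()
        if nd.rank in FACTOR_WEIGHTS and FACTOR_WEIGHTS[nd.rank] > 0
    ]
    factor_idx = {nid: i for i, nid in enumerate(factor_nodes)}
    membership = np.zeros((m, len(factor_nodes)))
    for j, otu in enumerate(otu_ids):
        lin = tree.otu_lineages[otu]
        for d in range(1, len(lin.names) + 1):
            pid = lin.path_id(d)
            if pid in factor_idx:
                membership[j, factor_idx[pid]] = FACTOR_WEIGHTS[tree.nodes[pid].rank]
    log_mu = np.log(base)[None, :] + np.where(in_clade, np.log(truth.effect_size), 0.0)[
        None, :
    ] * (labels_arr == "case").astype(float)[:, None]
    if noise > 0 and factor_nodes:
        eta = rng.normal(0.0, noise, size=(n, len(factor_nodes)))
        log_mu = log_mu + eta @ membership.T
    if noise > 0:
        log_mu = log_mu + rng.normal(0.0, noise, size=(n, m))
    rows = np.exp(log_mu)
    rows /= rows.sum(axis=1, keepdims=True)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    table = AbundanceTable(
        pd.DataFrame(rows, index=sample_ids, columns=otu_ids), normalized=True
    )
    labels = LabelVector(dict(zip(sample_ids, labels_arr)))
    return table, labels, truth


def simulate(
    n_otus: int = DEFAULTS["n_otus"],
    n_samples: int = DEFAULTS["n_samples"],
    branching: float | dict[Rank, float] | None = None,
    incomplete_fraction: float = DEFAULTS["incomplete_fraction"],
    effect_rank: Rank = DEFAULTS["effect_rank"],
    effect_size: float = DEFAULTS["effect_size"],
    noise: float = DEFAULTS["noise"],
    seed: int = 0,
) -> tuple[AbundanceTable, LabelVector, TaxonomyTree, SyntheticTruth]:
    """One-call scenario builder: taxonomy, planted truth, and dataset."""
    tree = random_taxonomy(n_otus, branching, incomplete_fraction, seed)
    rng = np.random.default_rng([seed, 13])
    base, _ = _base_proportions(tree.m, seed, DEFAULTS["base_sigma"])
    planted = choose_planted_node(
        tree, effect_rank, rng, abundance=dict(zip(tree.otu_ids, base))
    )
    truth = SyntheticTruth(
        planted_node=planted,
        effect_rank=effect_rank,
        effect_size=effect_size,
        incomplete_fraction=incomplete_fraction,
        n_samples=n_samples,
        n_otus=n_otus,
        seed=seed,
    )
    table, labels, truth = generate_dataset(tree, truth, noise=noise)
    return table, labels, tree, truth


def recovery_neighborhood(tree: TaxonomyTree, node_id: str) -> set[str]:
    """The taxon, its parent and its internal children — 'within one rank'."""
    node = tree.nodes[node_id]
    out = {node_id}
    if node.parent is not None and not node.parent.is_root:
        out.add(node.parent.id)
    out.update(child.id for child in node.children)
    return out
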