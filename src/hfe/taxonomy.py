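"""Greengenes-style lineage parsing and the rank-based taxonomy tree.

The hierarchy has eight levels: the seven canonical taxonomic ranks
(kingdom through species) plus an OTU level at the bottom.  OTUs whose
reference classification stops above species level ("leaves in incomplete
paths") attach directly below their deepest named taxon; they receive
special treatment in the feature-filtering pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


class Rank(enum.IntEnum):
    """Taxonomic level, totally ordered from kingdom (highest) to OTU (lowest)."""

    KINGDOM = 0
    PHYLUM = 1
    CLASS = 2
    ORDER = 3
    FAMILY = 4
    GENUS = 5
    SPECIES = 6
    OTU = 7


#: Greengenes single-letter prefixes for the seven named ranks.
RANK_PREFIXES: dict[Rank, str] = {
    Rank.KINGDOM: "k",
    Rank.PHYLUM: "p",
    Rank.CLASS: "c",
    Rank.ORDER: "o",
    Rank.FAMILY: "f",
    Rank.GENUS: "g",
    Rank.SPECIES: "s",
}

_PREFIX_TO_RANK = {v: k for k, v in RANK_PREFIXES.items()}

NAMED_RANKS: tuple[Rank, ...] = tuple(RANK_PREFIXES)


class LineageParseError(ValueError):
    """Raised when a lineage string violates the Greengenes dialect."""


@dataclass(frozen=True)
class Lineage:
    """An OTU's ordered chain of named taxa, kingdom downward.

    ``names`` holds the prefix-stripped taxon names for the contiguous run
    of named ranks starting at kingdom.  A lineage is *complete* when all
    seven ranks are named; placeholder tokens such as ``s__`` mark absent
    ranks and terminate the named run.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise LineageParseError("lineage has no named ranks")
        if len(self.names) > len(NAMED_RANKS):
            raise LineageParseError("lineage has more than 7 named ranks")

    @property
    def complete(self) -> bool:
        return len(self.names) == len(NAMED_RANKS)

    @property
    def deepest_rank(self) -> Rank:
        return NAMED_RANKS[len(self.names) - 1]

    @property
    def ranks(self) -> tuple[tuple[Rank, str], ...]:
        return tuple(zip(NAMED_RANKS, self.names))

    def format(self, sep: str = "; ") -> str:
        """Canonical Greengenes string: named ranks only, prefixes restored."""
        return sep.join(
            f"{RANK_PREFIXES[r]}__{n}" for r, n in zip(NAMED_RANKS, self.names)
        )

    def path_id(self, depth: int | None = None) -> str:
        """Unique node identifier for the taxon at ``depth`` (1-based; default deepest)."""
        if depth is None:
            depth = len(self.names)
        return self.format(sep=";")[: _path_len(self.names, depth)]


def _path_len(names: tuple[str, ...], depth: int) -> int:
    joined = ";".join(
        f"{RANK_PREFIXES[r]}__{n}" for r, n in zip(NAMED_RANKS[:depth], names[:depth])
    )
    return len(joined)


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-delimited Greengenes lineage string.

    Tokens use the ``k__``/``p__``/.../``s__`` prefixes in rank order
    starting at kingdom; whitespace around separators is ignored.  Empty
    names (e.g. a trailing ``s__``) mark the rank as absent — the lineage
    ends at the last named rank and is flagged incomplete.

    Raises
    ------
    LineageParseError
        If a token has a malformed prefix, ranks are out of order, or a
        named rank follows an unnamed one (a gap in the middle).
    """
    tokens = [t.strip() for t in text.split(";")]
    if not any(tokens):
        raise LineageParseError(f"empty lineage string: {text!r}")
    names: list[str] = []
    ended = False
    for pos, tok in enumerate(tokens):
        if tok == "":
            # allow trailing empty fields from e.g. "k__Bacteria; "
            ended = True
            continue
        if len(tok) < 3 or tok[1:3] != "__" or tok[0] not in _PREFIX_TO_RANK:
            raise LineageParseError(f"malformed rank token {tok!r} in {text!r}")
        rank = _PREFIX_TO_RANK[tok[0]]
        if rank != NAMED_RANKS[min(pos, len(NAMED_RANKS) - 1)] or pos >= len(NAMED_RANKS):
            raise LineageParseError(f"out-of-order rank token {tok!r} in {text!r}")
        name = tok[3:].strip()
        if name == "":
            ended = True  # placeholder: rank absent
            continue
        if ended:
            raise LineageParseError(
                f"named rank {tok!r} follows an unnamed rank in {text!r}"
            )
        names.append(name)
    if not names:
        raise LineageParseError(f"no named ranks in {text!r}")
    return Lineage(tuple(names))


@dataclass
class TaxonNode:
    """One named taxon in the tree (or the virtual super-root)."""

    id: str
    rank: Rank | None  # None only for the super-root
    name: str
    parent: "TaxonNode | None"
    children: list["TaxonNode"] = field(default_factory=list)
    otus: list[str] = field(default_factory=list)  # OTU leaves attached here

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonNode({self.id!r}, otus={len(self.otus)})"


class TaxonomyTree:
    """The 8-level hierarchy over which feature engineering operates.

    Internal nodes are the distinct named taxa across all lineages; their
    identifiers are full rank-prefixed paths (``k__Bacteria;p__Firmicutes;...``)
    so that a genus name recurring under different families stays unique.
    A virtual super-root above kingdom makes multi-kingdom tables a single
    tree; it is never a candidate feature and is excluded from ``m_prime``.
    """

    def __init__(self) -> None:
        self.root = TaxonNode(id="<root>", rank=None, name="<root>", parent=None)
        self.nodes: dict[str, TaxonNode] = {}
        self.otu_attachment: dict[str, TaxonNode] = {}
        self.otu_lineages: dict[str, Lineage] = {}

    @property
    def otu_ids(self) -> list[str]:
        return list(self.otu_attachment)

    @property
    def m(self) -> int:
        """Number of OTU features."""
        return len(self.otu_attachment)

    @property
    def m_prime(self) -> int:
        """Number of internal (named-taxon) nodes, super-root excluded."""
        return len(self.nodes)

    @property
    def internal_ids(self) -> list[str]:
        """Internal node identifiers in deterministic (insertion) order."""
        return list(self.nodes)

    def edges(self) -> Iterator[tuple[TaxonNode, str]]:
        """Yield (parent_node, child_feature_id) for every candidate-feature child.

        Children are internal taxa or OTU leaves; edges out of the
        super-root are skipped because kingdom nodes have no parent feature.
        """
        for node in self.nodes.values():
            for child in node.children:
                yield node, child.id
            for otu in node.otus:
                yield node, otu

    def lineage_path(self, otu_id: str) -> list[str]:
        """Internal-node ids from kingdom down to the OTU's attachment node."""
        lin = self.otu_lineages[otu_id]
        return [lin.path_id(d) for d in range(1, len(lin.names) + 1)]

    def incomplete_leaves(self) -> set[str]:
        """OTUs whose lineage is not named all the way down to species."""
        return {o for o, lin in self.otu_lineages.items() if not lin.complete}

    def _get_or_add(self, lineage: Lineage, depth: int) -> TaxonNode:
        pid = lineage.path_id(depth)
        node = self.nodes.get(pid)
        if node is None:
            parent = self.root if depth == 1 else self._get_or_add(lineage, depth - 1)
            node = TaxonNode(
                id=pid,
                rank=NAMED_RANKS[depth - 1],
                name=lineage.names[depth - 1],
                parent=parent,
            )
            parent.children.append(node)
            self.nodes[pid] = node
        return node


def build_tree(
    otu_ids: Iterable[str], lineages: Mapping[str, Lineage | str]
) -> TaxonomyTree:
    """Assemble the taxonomy tree for a set of OTUs.

    Identical (rank, name) path prefixes merge into a single node; each OTU
    attaches as a leaf under its deepest named taxon.  Lineages may be given
    as parsed :class:`Lineage` objects or raw Greengenes strings.

    Raises
    ------
    ValueError
        On duplicate or missing OTU ids, or empty input.
    """
    otu_ids = list(otu_ids)
    if not otu_ids:
        raise ValueError("no OTU ids given")
    if len(set(otu_ids)) != len(otu_ids):
        dupes = sorted({o for o in otu_ids if otu_ids.count(o) > 1})
        raise ValueError(f"duplicate OTU ids: {dupes[:5]}")
    tree = TaxonomyTree()
    for otu in otu_ids:
        if otu not in lineages:
            raise ValueError(f"OTU {otu!r} has no lineage")
        lin = lineages[otu]
        if isinstance(lin, str):
            lin = parse_lineage(lin)
        attach = tree._get_or_add(lin, len(lin.names))
        attach.otus.append(otu)
        tree.otu_attachment[otu] = attach
        tree.otu_lineages[otu] = lin
    return tree


def incomplete_leaves(tree: TaxonomyTree) -> set[str]:
    """OTU ids that are leaves in incomplete paths (lineage stops above species)."""
    return tree.incomplete_leaves()
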