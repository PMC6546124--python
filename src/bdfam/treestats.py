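"""Rooted-tree I/O and per-clade branch-length statistics.

A gene-family phylogram can be summarised clade by clade: the cumulative
branch length (CBL) of a clade is the sum of every branch strictly inside
the subtree spanned by its members; dividing by the number of member
sequences gives the normalized CBL, and adding the internal branches on
the path from the tree root down to the clade's most recent common
ancestor (MRCA) gives the cumulative patristic distance (CPD).  Fast-
evolving ("unstable") gene lineages accumulate more substitutions and so
show larger values of all three statistics than slow, conserved lineages.

Trees are parsed and written with :mod:`dendropy`; the :class:`PhyloTree`
wrapper enforces the invariants this package relies on (single root,
nonnegative branch lengths, unique nonempty tip labels) and exposes the
small traversal surface the statistics need.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "NonMonophyleticCladeError",
    "PhyloTree",
    "CladeBranchStats",
    "parse_newick",
    "write_newick",
    "mrca",
    "is_monophyletic",
    "cumulative_branch_length",
    "normalized_cbl",
    "cumulative_patristic_distance",
    "clade_stats_table",
    "stats_to_frame",
    "read_clade_assignment",
    "read_species_map",
    "write_stats_tsv",
]


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced, duplicate tips, bad lengths...)."""


class TreeValidationError(ValueError):
    """A structurally valid tree violating a PhyloTree invariant."""


class NonMonophyleticCladeError(ValueError):
    """Clade members do not form a monophyletic group on the tree."""


class PhyloTree:
    """A rooted tree with nonnegative branch lengths and unique tip labels.

    Thin wrapper over a :class:`dendropy.Tree`.  Branch lengths are
    materialised as floats at construction time (a missing length becomes
    0.0; see :func:`parse_newick` for the warning/error policy), so every
    downstream computation can assume ``node.edge.length`` is a
    nonnegative float, with the root's own edge fixed at 0.0.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        self._materialize_lengths()
        self._validate()
        self._tip_index = {
            leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
        }

    # -- construction / serialisation ------------------------------------

    @classmethod
    def from_newick(cls, text: str, missing_length: str = "zero") -> "PhyloTree":
        return parse_newick(text, missing_length=missing_length)

    def write_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier="",
            ).strip()
        )

    # -- invariants -------------------------------------------------------

    def _materialize_lengths(self) -> None:
        for node in self._tree:
            if node.edge.length is None:
                node.edge.length = 0.0
        self._tree.seed_node.edge.length = 0.0

    def _validate(self) -> None:
        labels: list[str] = []
        for node in self._tree:
            if node.edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {node.edge.length} on edge to "
                    f"{_node_label(node) or '<unlabeled node>'}"
                )
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeValidationError("tree contains an unlabeled tip")
                labels.append(node.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")

    # -- traversal surface ------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    def tip(self, label: str) -> dendropy.Node:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of ``tips``; a single tip is its own MRCA."""
        tips = list(tips)
        if not tips:
            raise ValueError("mrca of an empty tip set is undefined")
        nodes = [self.tip(t) for t in tips]
        # intersect root-ward paths; the deepest shared node is the MRCA
        common: set[int] | None = None
        by_id: dict[int, dendropy.Node] = {}
        for node in nodes:
            path = []
            cur = node
            while cur is not None:
                by_id[id(cur)] = cur
                path.append(id(cur))
                cur = cur.parent_node
            common = set(path) if common is None else common & set(path)
        cur = nodes[0]
        while id(cur) not in common:  # type: ignore[operator]
            cur = cur.parent_node
        return cur

    def leaf_labels_below(self, node: dendropy.Node) -> set[str]:
        return {leaf.taxon.label for leaf in node.leaf_iter()}

    def subtree_branch_sum(self, node: dendropy.Node) -> float:
        """Sum of branch lengths strictly below ``node`` (its own edge excluded)."""
        total = 0.0
        for nd in node.preorder_iter():
            if nd is not node:
                total += nd.edge.length
        return total

    def root_path_length(self, node: dendropy.Node, include_stem: bool = True) -> float:
        """Branch length along the path root → ``node``.

        With ``include_stem`` the node's own subtending edge counts;
        without it only the edges strictly above the node do.
        """
        total = node.edge.length if include_stem else 0.0
        cur = node.parent_node
        while cur is not None:
            total += cur.edge.length
            cur = cur.parent_node
        return total

    def __len__(self) -> int:
        return len(self._tip_index)


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def parse_newick(text: str, missing_length: str = "zero") -> PhyloTree:
    """Parse a single rooted Newick statement.

    Parameters
    ----------
    text:
        One Newick statement terminated by ``;``.  Quoted labels and
        ``[...]`` comments are handled by the underlying reader.
    missing_length:
        ``"zero"`` (default) substitutes 0.0 for absent branch lengths and
        warns; ``"error"`` raises :class:`NewickParseError` instead.
    """
    if missing_length not in ("zero", "error"):
        raise ValueError("missing_length must be 'zero' or 'error'")
    if not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise NewickParseError(str(exc)) from exc
    missing = [
        _node_label(nd) or "<internal>"
        for nd in tree
        if nd.edge.length is None and nd.parent_node is not None
    ]
    if missing:
        msg = f"{len(missing)} edge(s) without branch length (e.g. {missing[0]!r})"
        if missing_length == "error":
            raise NewickParseError(msg)
        warnings.warn(msg + "; treating as 0", stacklevel=2)
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    return tree.write_newick()


def mrca(tree: PhyloTree, tips: Iterable[str]) -> dendropy.Node:
    return tree.mrca(tips)


def is_monophyletic(tree: PhyloTree, clade_tips: Iterable[str]) -> bool:
    clade = set(clade_tips)
    return tree.leaf_labels_below(tree.mrca(clade)) == clade


def _clade_mrca(tree: PhyloTree, clade_tips: Iterable[str], force_mrca: bool):
    clade = set(clade_tips)
    if not clade:
        raise ValueError("clade_tips must be nonempty")
    node = tree.mrca(clade)
    below = tree.leaf_labels_below(node)
    mono = below == clade
    if not mono:
        extra = sorted(below - clade)
        if not force_mrca:
            raise NonMonophyleticCladeError(
                f"clade is not monophyletic: MRCA subtree also contains {extra}"
            )
        warnings.warn(
            f"non-monophyletic clade; computing over full MRCA subtree "
            f"(includes {extra})",
            stacklevel=3,
        )
    return node, mono


def cumulative_branch_length(
    tree: PhyloTree, clade_tips: Iterable[str], force_mrca: bool = False
) -> float:
    """Sum of branch lengths strictly within the clade (its stem edge excluded).

    Every terminal and internal edge below the clade MRCA contributes; a
    single-tip clade therefore has CBL 0.  Non-monophyletic tip sets raise
    unless ``force_mrca``, in which case the full MRCA subtree is used.
    """
    node, _ = _clade_mrca(tree, clade_tips, force_mrca)
    return tree.subtree_branch_sum(node)


def normalized_cbl(cbl: float, n_seqs: int) -> float:
    """CBL divided by the number of member sequences."""
    if n_seqs < 1:
        raise ValueError(f"n_seqs must be >= 1, got {n_seqs}")
    if cbl < 0:
        raise ValueError(f"cbl must be nonnegative, got {cbl}")
    return cbl / n_seqs


def cumulative_patristic_distance(
    tree: PhyloTree,
    clade_tips: Iterable[str],
    include_stem: bool = True,
    force_mrca: bool = False,
) -> float:
    """CBL plus the branch length on the path from the root to the clade MRCA.

    The MRCA's own subtending (stem) edge is counted by default — the node
    supporting the clade is reached via its stem; ``include_stem=False``
    gives the exclusive convention.  When the MRCA is the root the CPD
    equals the CBL under either convention.
    """
    node, _ = _clade_mrca(tree, clade_tips, force_mrca)
    return tree.subtree_branch_sum(node) + tree.root_path_length(
        node, include_stem=include_stem
    )


@dataclass(frozen=True)
class CladeBranchStats:
    """Branch-length summary for one clade of a phylogram."""

    clade_id: str
    n_seqs: int
    cbl: float
    normalized_cbl: float
    cpd: float
    monophyletic: bool

    def __post_init__(self):
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")
        if self.cbl < 0 or self.cpd < -1e-12:
            raise ValueError("branch-length statistics must be nonnegative")


def clade_stats_table(
    tree: PhyloTree,
    clade_assignment: Mapping[str, str],
    include_stem: bool = True,
    force_mrca: bool = False,
) -> list[CladeBranchStats]:
    """Per-clade CBL / normalized CBL / CPD for a full tip partition.

    ``clade_assignment`` maps every tip label to a clade id; an
    unassigned tip is an error.  Records are returned sorted by clade id.
    """
    unassigned = sorted(set(tree.tip_labels) - set(clade_assignment))
    if unassigned:
        raise ValueError(f"tips missing from clade assignment: {unassigned}")
    members: dict[str, set[str]] = {}
    for tip in tree.tip_labels:
        members.setdefault(str(clade_assignment[tip]), set()).add(tip)
    out = []
    for clade_id in sorted(members):
        tips = members[clade_id]
        node, mono = _clade_mrca(tree, tips, force_mrca)
        cbl = tree.subtree_branch_sum(node)
        cpd = cbl + tree.root_path_length(node, include_stem=include_stem)
        out.append(
            CladeBranchStats(
                clade_id=clade_id,
                n_seqs=len(tips),
                cbl=cbl,
                normalized_cbl=normalized_cbl(cbl, len(tips)),
                cpd=cpd,
                monophyletic=mono,
            )
        )
    return out


# -- tabular I/O ----------------------------------------------------------


def stats_to_frame(stats: Sequence[CladeBranchStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clade_id": s.clade_id,
                "n_seqs": s.n_seqs,
                "cbl": s.cbl,
                "normalized_cbl": s.normalized_cbl,
                "cpd": s.cpd,
                "monophyletic": s.monophyletic,
            }
            for s in stats
        ]
    )


def read_clade_assignment(path) -> dict[str, str]:
    """Read a two-column TSV (``gene_id``, ``clade_id``) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "clade_id"):
        if col not in df.columns:
            raise ValueError(f"clade assignment table lacks column {col!r}")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"])
        raise ValueError(f"duplicate gene_id rows in clade assignment: {dupes}")
    return dict(zip(df["gene_id"], df["clade_id"]))


def read_species_map(path) -> pd.DataFrame:
    """Read a gene→species TSV with an optional 0/1 ``pseudogene`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "species_id": str})
    for col in ("gene_id", "species_id"):
        if col not in df.columns:
            raise ValueError(f"species map lacks column {col!r}")
    if "pseudogene" not in df.columns:
        df["pseudogene"] = 0
    df["pseudogene"] = df["pseudogene"].fillna(0).astype(int)
    if not df["pseudogene"].isin((0, 1)).all():
        raise ValueError("pseudogene column must be 0/1")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"])
        raise ValueError(f"duplicate gene_id rows in species map: {dupes}")
    return df[["gene_id", "species_id", "pseudogene"]]


def write_stats_tsv(stats: Sequence[CladeBranchStats], path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False)
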