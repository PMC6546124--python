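"""Gene-family content analysis: copy-number matrices, stability, Dollo events.

A gene family evolving by birth and death is summarised as a clade ×
species matrix of functional copy counts (pseudogenes tallied apart).
From that matrix this module derives

* **stability calls** — a clade is *stable* when every sampled genome
  retains at least one functional copy, *unstable* otherwise;
* **Dollo gain/loss reconstructions** — each clade originates exactly
  once (at the MRCA, on the species tree, of the species carrying it)
  and can only be lost thereafter; the minimal loss placement is the
  unique set of maximal all-absent subtrees below the origin;
* **ancestral repertoire sizes** — how many clades were carried by each
  ancestral species-tree node, and the arithmetic lower bound obtained
  by discounting clades created by lineage-specific duplications.

A packaged fixture (`far_clades.tsv` + `drosophila12.nwk`) encodes the
fatty acyl-CoA reductase (FAR) repertoire of the 12 sequenced
*Drosophila* genomes: 12 stable clades, 6 unstable ones with the
documented presence/pseudogene patterns, RNAi-lethality annotations and
the three melanogaster-group-specific duplicate clades.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .treestats import PhyloTree, parse_newick, read_clade_assignment, read_species_map

__all__ = [
    "CopyNumberMatrix",
    "StabilityCall",
    "GainLossEvents",
    "build_copy_matrix",
    "classify_stability",
    "dollo_reconstruct",
    "ancestral_repertoire",
    "ancestral_counts",
    "repertoire_lower_bound",
    "lethality_proportions",
    "ensure_node_labels",
    "load_far_fixture",
    "load_drosophila_tree",
    "far_fixture_gene_table",
    "stability_to_frame",
    "events_to_frame",
]


@dataclass
class CopyNumberMatrix:
    """Clade × species counts of functional copies and pseudogenes."""

    counts: pd.DataFrame
    pseudo_counts: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.pseudo_counts.index) or not (
            self.counts.columns.equals(self.pseudo_counts.columns)
        ):
            raise ValueError("counts and pseudo_counts must share clades and species")
        if (self.counts.values < 0).any() or (self.pseudo_counts.values < 0).any():
            raise ValueError("copy counts must be nonnegative")
        empty = (self.counts.values + self.pseudo_counts.values).sum(axis=1) == 0
        if empty.any():
            bad = list(self.counts.index[empty])
            raise ValueError(f"clades with no gene or pseudogene anywhere: {bad}")

    @property
    def clades(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self, count_pseudogenes: bool = False) -> pd.DataFrame:
        """Boolean clade × species presence, optionally counting pseudogenes."""
        total = self.counts + (self.pseudo_counts if count_pseudogenes else 0)
        return total >= 1


def build_copy_matrix(
    gene_species_map: pd.DataFrame,
    clade_assignment: Mapping[str, str] | pd.DataFrame,
) -> CopyNumberMatrix:
    """Cross-tabulate per-gene tables into a CopyNumberMatrix.

    ``gene_species_map`` needs columns ``gene_id``, ``species_id`` and an
    optional 0/1 ``pseudogene`` column; ``clade_assignment`` maps each
    gene to its clade.  A gene present in one table but not the other is
    an error (orphans are listed).
    """
    gs = gene_species_map.copy()
    if "pseudogene" not in gs.columns:
        gs["pseudogene"] = 0
    if isinstance(clade_assignment, pd.DataFrame):
        clade_assignment = dict(
            zip(clade_assignment["gene_id"], clade_assignment["clade_id"])
        )
    genes = set(gs["gene_id"])
    assigned = set(clade_assignment)
    orphans = sorted(genes ^ assigned)
    if orphans:
        raise ValueError(
            f"genes present in only one of species map / clade assignment: {orphans}"
        )
    gs["clade_id"] = gs["gene_id"].map(clade_assignment)
    clades = sorted(gs["clade_id"].unique())
    species = sorted(gs["species_id"].unique())
    counts = pd.DataFrame(0, index=clades, columns=species, dtype=int)
    pseudo = counts.copy()
    for _, row in gs.iterrows():
        target = pseudo if row["pseudogene"] else counts
        target.loc[row["clade_id"], row["species_id"]] += 1
    return CopyNumberMatrix(counts=counts, pseudo_counts=pseudo)


@dataclass(frozen=True)
class StabilityCall:
    clade_id: str
    status: str  # "stable" | "unstable"
    n_species_present: int
    missing_species: tuple[str, ...]


def classify_stability(
    matrix: CopyNumberMatrix, count_pseudogenes: bool = False
) -> list[StabilityCall]:
    """Stable = at least one copy in every sampled genome.

    Pseudogenes do not establish presence unless ``count_pseudogenes``:
    a genome whose only copy is pseudogenized has lost the functional
    gene and the clade's content is variable.
    """
    pres = matrix.presence(count_pseudogenes)
    calls = []
    n_species = len(matrix.species)
    for clade in matrix.clades:
        row = pres.loc[clade]
        missing = tuple(s for s in matrix.species if not row[s])
        n_present = n_species - len(missing)
        calls.append(
            StabilityCall(
                clade_id=clade,
                status="stable" if n_present == n_species else "unstable",
                n_species_present=n_present,
                missing_species=missing,
            )
        )
    return calls


# -- Dollo reconstruction -------------------------------------------------


@dataclass(frozen=True)
class GainLossEvents:
    """Single-origin (Dollo) reconstruction of one clade on the species tree.

    ``losses`` holds the child-node label of each edge on which the clade
    was lost; ``presence`` flags, for every species-tree node, whether the
    clade was carried there.
    """

    clade_id: str
    origin_node: str
    losses: tuple[str, ...]
    presence: Mapping[str, bool] = field(hash=False)

    @property
    def n_losses(self) -> int:
        return len(self.losses)


def ensure_node_labels(tree: PhyloTree, prefix: str = "N") -> PhyloTree:
    """Assign ``N1..`` labels (preorder) to unlabeled internal nodes, in place."""
    i = 0
    seen = {t for t in tree.tip_labels}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            i += 1
            while f"{prefix}{i}" in seen:
                i += 1
            node.label = f"{prefix}{i}"
        seen.add(node.label)
    labels = [n.label for n in tree.dendropy_tree.preorder_internal_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("internal node labels are not unique")
    return tree


def _node_name(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def dollo_reconstruct(
    matrix: CopyNumberMatrix,
    species_tree: PhyloTree,
    count_pseudogenes: bool = False,
    origin_at_root: Iterable[str] = (),
) -> list[GainLossEvents]:
    """Minimal single-origin gain/loss reconstruction for every clade.

    The origin is the species-tree MRCA of the species carrying the
    clade; losses are the maximal all-absent subtrees below the origin —
    a decomposition that is unique, so no tie-breaking is needed.  Clades
    named in ``origin_at_root`` are forced to originate at the tree root
    instead (the convention used when outgroup evidence places a clade
    deeper than its extant distribution implies), which can only add
    losses.
    """
    ensure_node_labels(species_tree)
    tree_tips = set(species_tree.tip_labels)
    if tree_tips != set(matrix.species):
        raise ValueError(
            "species tree tips and matrix species differ: "
            f"tree-only={sorted(tree_tips - set(matrix.species))}, "
            f"matrix-only={sorted(set(matrix.species) - tree_tips)}"
        )
    force_root = set(origin_at_root)
    pres = matrix.presence(count_pseudogenes)
    events = []
    for clade in matrix.clades:
        present = {s for s in matrix.species if pres.loc[clade, s]}
        if not present:
            raise ValueError(f"clade {clade!r} has zero presence; cannot reconstruct")
        origin = (
            species_tree.root
            if clade in force_root
            else species_tree.mrca(present)
        )
        # post-order: a subtree is all-absent iff every leaf below is absent
        all_absent: dict[int, bool] = {}
        for node in origin.postorder_iter():
            if node.is_leaf():
                all_absent[id(node)] = node.taxon.label not in present
            else:
                all_absent[id(node)] = all(
                    all_absent[id(c)] for c in node.child_nodes()
                )
        losses = []
        presence_flags: dict[str, bool] = {}
        for node in species_tree.dendropy_tree.preorder_node_iter():
            name = _node_name(node)
            if id(node) not in all_absent:  # outside the origin subtree
                presence_flags[name] = False
        for node in origin.preorder_iter():
            parent_lost = (
                node is not origin
                and not presence_flags[_node_name(node.parent_node)]
            )
            if parent_lost:
                presence_flags[_node_name(node)] = False
            elif node is not origin and all_absent[id(node)]:
                losses.append(_node_name(node))
                presence_flags[_node_name(node)] = False
            else:
                presence_flags[_node_name(node)] = True
        events.append(
            GainLossEvents(
                clade_id=clade,
                origin_node=_node_name(origin),
                losses=tuple(sorted(losses)),
                presence=presence_flags,
            )
        )
    return events


def ancestral_repertoire(events: Sequence[GainLossEvents], node: str) -> int:
    """Number of clades carried at a species-tree node."""
    for ev in events:
        if node not in ev.presence:
            raise KeyError(f"node {node!r} not on the species tree of {ev.clade_id}")
    return sum(1 for ev in events if ev.presence[node])


def ancestral_counts(
    events: Sequence[GainLossEvents], species_tree: PhyloTree
) -> pd.DataFrame:
    """Repertoire size at every node, preorder, as a two-column table."""
    ensure_node_labels(species_tree)
    rows = [
        {
            "node_label": _node_name(node),
            "repertoire_size": ancestral_repertoire(events, _node_name(node)),
        }
        for node in species_tree.dendropy_tree.preorder_node_iter()
    ]
    return pd.DataFrame(rows)


def repertoire_lower_bound(n_clades: int, n_lineage_specific_duplicates: int) -> int:
    """Lower bound on the ancestral repertoire: total clades minus those
    created by duplications confined to one species group (each such
    duplication adds one excess clade relative to the ancestor)."""
    if not 0 <= n_lineage_specific_duplicates <= n_clades:
        raise ValueError(
            "need 0 <= n_lineage_specific_duplicates <= n_clades, got "
            f"{n_lineage_specific_duplicates} of {n_clades}"
        )
    return n_clades - n_lineage_specific_duplicates


def lethality_proportions(
    annotations: pd.DataFrame, calls: Sequence[StabilityCall]
) -> pd.DataFrame:
    """Tally RNAi-lethality by stability class.

    ``annotations`` needs ``clade_id`` and ``rnai_lethal`` (1/0, NaN =
    untested).  Returns per-status ``n_tested``, ``n_lethal`` and
    ``proportion_lethal``; clades without an RNAi phenotype are excluded
    from the denominator.
    """
    status = {c.clade_id: c.status for c in calls}
    df = annotations[["clade_id", "rnai_lethal"]].dropna(subset=["rnai_lethal"]).copy()
    df["status"] = df["clade_id"].map(status)
    if df["status"].isna().any():
        missing = sorted(df.loc[df["status"].isna(), "clade_id"])
        raise ValueError(f"clades without a stability call: {missing}")
    out = (
        df.groupby("status")["rnai_lethal"]
        .agg(n_tested="count", n_lethal="sum")
        .reset_index()
    )
    out["n_lethal"] = out["n_lethal"].astype(int)
    out["proportion_lethal"] = out["n_lethal"] / out["n_tested"]
    return out


# -- packaged Drosophila FAR fixture --------------------------------------


def _data_path(name: str):
    return importlib.resources.files("bdfam") / "data" / name


def load_drosophila_tree() -> PhyloTree:
    """The 12-species *Drosophila* time tree (branch lengths in My)."""
    text = _data_path("drosophila12.nwk").read_text()
    return ensure_node_labels(parse_newick(text))


def load_far_fixture() -> tuple[CopyNumberMatrix, pd.DataFrame]:
    """The 18-clade FAR presence/pseudogene matrix plus clade annotations.

    Returns the CopyNumberMatrix over the 12 genomes and a per-clade
    annotation frame with ``lineage_specific_duplicate`` (0/1) and
    ``rnai_lethal`` (1/0/NaN for the clade with no melanogaster member).
    """
    df = pd.read_csv(_data_path("far_clades.tsv"), sep="\t")
    counts = df.pivot(index="clade_id", columns="species_id", values="n_genes")
    pseudo = df.pivot(index="clade_id", columns="species_id", values="n_pseudogenes")
    matrix = CopyNumberMatrix(
        counts=counts.astype(int), pseudo_counts=pseudo.astype(int)
    )
    ann = (
        df.groupby("clade_id")[["lineage_specific_duplicate", "rnai_lethal"]]
        .first()
        .reset_index()
    )
    return matrix, ann


def far_fixture_gene_table() -> pd.DataFrame:
    """Expand the fixture matrix to per-gene rows.

    Synthesizes one row per gene copy (``gene_id``, ``species_id``,
    ``clade_id``, ``pseudogene``) with deterministic ids, matching the
    gene-level TSV interfaces of the pipeline.
    """
    matrix, _ = load_far_fixture()
    rows = []
    for clade in matrix.clades:
        for sp in matrix.species:
            k = 0
            for _ in range(int(matrix.counts.loc[clade, sp])):
                k += 1
                rows.append((f"{sp}_{clade}_{k}", sp, clade, 0))
            for _ in range(int(matrix.pseudo_counts.loc[clade, sp])):
                k += 1
                rows.append((f"{sp}_{clade}_{k}", sp, clade, 1))
    return pd.DataFrame(
        rows, columns=["gene_id", "species_id", "clade_id", "pseudogene"]
    )


# -- tabular output -------------------------------------------------------


def stability_to_frame(calls: Sequence[StabilityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clade_id": c.clade_id,
                "status": c.status,
                "n_species_present": c.n_species_present,
                "missing_species": ",".join(c.missing_species),
            }
            for c in calls
        ]
    )


def events_to_frame(events: Sequence[GainLossEvents]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clade_id": e.clade_id,
                "origin_node_label": e.origin_node,
                "loss_edges": ",".join(e.losses),
                "n_losses": e.n_losses,
            }
            for e in events
        ]
    )
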