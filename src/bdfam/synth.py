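"""Duplication–loss gene-family simulator with known truth.

Simulates gene-family evolution along a rooted species tree (branch
lengths in time units) under a linear birth–death process: each gene
lineage independently duplicates at rate λ and is lost at rate μ per
unit time, and every extant lineage is copied into both daughter edges
at each speciation.  Clades come in two classes mirroring the
birth-and-death model of multigene families: *stable* clades (λ = μ = 0,
baseline substitution rate) persist as single-copy orthologs, while
*unstable* clades turn over and, via a substitution-rate multiplier r,
accumulate branch length faster on the emitted gene trees (branch length
= elapsed time × r, in substitutions/site-like units).

A copy lost on a terminal edge is, with probability ``pseudogene_prob``,
emitted as a pseudogene tip truncated at the loss time instead of being
pruned — emulating recognizable pseudogenized copies in extant genomes;
losses on internal edges leave no trace, as ancient pseudogenes decay
beyond recognition.

The simulation is event-driven (Gillespie), so the exact per-edge event
log is available as ground truth for validating Dollo reconstructions
and stability calls downstream.  One child random stream is spawned per
clade from the single global seed, so adding clades never perturbs
existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .family_events import CopyNumberMatrix, ensure_node_labels, load_drosophila_tree
from .treestats import PhyloTree, parse_newick

__all__ = [
    "ClassRates",
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_family",
    "write_family",
    "read_family",
    "default_species_tree",
]


@dataclass(frozen=True)
class ClassRates:
    """Birth–death parameters for one clade class.

    duplication_rate and loss_rate are per lineage per unit time;
    rate_multiplier converts time to gene-tree branch length
    (substitutions/site per unit time relative to the baseline).
    """

    duplication_rate: float
    loss_rate: float
    rate_multiplier: float

    def __post_init__(self):
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.rate_multiplier <= 0:
            raise ValueError("rate_multiplier must be positive")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated gene family.

    Defaults emulate the *Drosophila* FAR setting: a 12-species time tree
    of ~63 My depth, 12 single-copy stable clades and 6 unstable clades
    with duplication/loss turnover and doubled substitution rate.
    """

    seed: int
    species_tree: PhyloTree | None = None  # default: packaged Drosophila tree
    n_stable_clades: int = 12
    n_unstable_clades: int = 6
    stable: ClassRates = field(
        default_factory=lambda: ClassRates(0.0, 0.0, 1.0)
    )
    unstable: ClassRates = field(
        default_factory=lambda: ClassRates(0.05, 0.05, 2.0)
    )
    pseudogene_prob: float = 0.1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.n_stable_clades < 0 or self.n_unstable_clades < 0:
            raise ValueError("clade counts must be nonnegative")
        if not 0 <= self.pseudogene_prob <= 1:
            raise ValueError("pseudogene_prob must be a probability")

    def resolved_tree(self) -> PhyloTree:
        tree = self.species_tree or default_species_tree()
        for node in tree.dendropy_tree:
            if node.parent_node is not None and node.edge.length <= 0:
                raise ValueError(
                    "species tree must have positive branch lengths for simulation"
                )
        return ensure_node_labels(tree)

    def to_jsonable(self) -> dict:
        d = {
            "seed": self.seed,
            "species_tree": (self.species_tree or default_species_tree()).write_newick(),
            "n_stable_clades": self.n_stable_clades,
            "n_unstable_clades": self.n_unstable_clades,
            "stable": dataclasses.asdict(self.stable),
            "unstable": dataclasses.asdict(self.unstable),
            "pseudogene_prob": self.pseudogene_prob,
        }
        return d


def default_species_tree() -> PhyloTree:
    return load_drosophila_tree()


@dataclass
class SimulatedFamily:
    """One simulated data set: gene trees, copy matrix, and ground truth."""

    gene_trees: dict[str, PhyloTree]
    matrix: CopyNumberMatrix
    truth: dict[str, str]  # clade -> "stable" | "unstable"
    extinct: tuple[str, ...]
    event_log: pd.DataFrame  # clade_id, edge (child label), duplications, losses
    gene_table: pd.DataFrame  # gene_id, species_id, clade_id, pseudogene
    config: SimulationConfig


class _GNode:
    __slots__ = ("label", "length", "children", "pseudo", "species")

    def __init__(self, label="", length=0.0, children=None, pseudo=False, species=None):
        self.label = label
        self.length = length
        self.children = children or []
        self.pseudo = pseudo
        self.species = species

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length!r}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}){self.label}:{self.length!r}"

    def tips(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.tips()


def _simulate_clade(clade_id, rates, species_root, rng, pseudogene_prob, log):
    """Gillespie simulation of one clade; returns the gene-tree root or None."""
    lam, mu, r = rates.duplication_rate, rates.loss_rate, rates.rate_multiplier
    total = lam + mu
    counters: dict[str, int] = {}

    def tip(species_label: str, pseudo: bool) -> _GNode:
        k = counters.get(species_label, 0) + 1
        counters[species_label] = k
        suffix = "p" if pseudo else "g"
        return _GNode(
            label=f"{species_label}_{clade_id}_{suffix}{k}",
            pseudo=pseudo,
            species=species_label,
        )

    def run_lineage(sp_node, t_remaining: float, elapsed: float):
        """One gene lineage entering the species-tree edge above ``sp_node``
        with ``t_remaining`` time left on it; ``elapsed`` is survived time
        since the lineage's last retained branching point (may span edges)."""
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if wait < t_remaining:
                t_remaining -= wait
                elapsed += wait
                if rng.random() < lam / total:  # duplication
                    log[(clade_id, sp_node.label if sp_node.taxon is None else sp_node.taxon.label)][0] += 1
                    left = run_lineage(sp_node, t_remaining, 0.0)
                    right = run_lineage(sp_node, t_remaining, 0.0)
                    kids = [k for k in (left, right) if k is not None]
                    if not kids:
                        return None
                    if len(kids) == 1:
                        kids[0].length += elapsed * r
                        return kids[0]
                    return _GNode(length=elapsed * r, children=kids)
                # loss
                log[(clade_id, sp_node.label if sp_node.taxon is None else sp_node.taxon.label)][1] += 1
                if sp_node.is_leaf() and rng.random() < pseudogene_prob:
                    node = tip(sp_node.taxon.label, pseudo=True)
                    node.length = elapsed * r
                    return node
                return None
            # survived to the bottom of the edge
            elapsed += t_remaining
            if sp_node.is_leaf():
                node = tip(sp_node.taxon.label, pseudo=False)
                node.length = elapsed * r
                return node
            kids = []
            for child in sp_node.child_nodes():
                sub = run_lineage(child, child.edge.length, 0.0)
                if sub is not None:
                    kids.append(sub)
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += elapsed * r
                return kids[0]
            return _GNode(length=elapsed * r, children=kids)

    kids = []
    for child in species_root.child_nodes():
        sub = run_lineage(child, child.edge.length, 0.0)
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:
        root = kids[0]
    else:
        root = _GNode(length=0.0, children=kids)
    root.length = 0.0
    return root


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Simulate every clade of the family along the species tree."""
    tree = config.resolved_tree()
    species = sorted(tree.tip_labels)
    clades = [(f"S{i + 1:02d}", "stable") for i in range(config.n_stable_clades)] + [
        (f"U{i + 1:02d}", "unstable") for i in range(config.n_unstable_clades)
    ]
    streams = np.random.SeedSequence(config.seed).spawn(len(clades))
    edge_labels = [
        (nd.taxon.label if nd.taxon is not None else nd.label)
        for nd in tree.dendropy_tree.preorder_node_iter()
        if nd.parent_node is not None
    ]

    gene_trees: dict[str, PhyloTree] = {}
    truth: dict[str, str] = {}
    extinct: list[str] = []
    gene_rows = []
    log: dict[tuple[str, str], list[int]] = {}
    for (clade_id, cls), ss in zip(clades, streams):
        truth[clade_id] = cls
        for e in edge_labels:
            log[(clade_id, e)] = [0, 0]
        rates = config.stable if cls == "stable" else config.unstable
        rng = np.random.default_rng(ss)
        root = _simulate_clade(
            clade_id, rates, tree.root, rng, config.pseudogene_prob, log
        )
        tips = list(root.tips()) if root is not None else []
        if not any(not t.pseudo for t in tips):
            # no functional copy survives anywhere: the clade is extinct
            # (pseudogene-only survivors are still emitted for bookkeeping)
            extinct.append(clade_id)
        if not tips:
            continue
        if len(tips) == 1:
            # single-tip family: serialize as a trivial one-leaf tree
            newick = f"({tips[0].newick()}):0.0;"
        else:
            newick = root.newick() + ";"
        gene_trees[clade_id] = parse_newick(newick)
        for t in tips:
            gene_rows.append((t.label, t.species, clade_id, int(t.pseudo)))

    gene_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "species_id", "clade_id", "pseudogene"]
    )
    surviving = sorted(gene_trees)
    counts = pd.DataFrame(0, index=surviving, columns=species, dtype=int)
    pseudo = counts.copy()
    for _, row in gene_table.iterrows():
        target = pseudo if row["pseudogene"] else counts
        target.loc[row["clade_id"], row["species_id"]] += 1
    matrix = CopyNumberMatrix(counts=counts, pseudo_counts=pseudo)
    event_log = pd.DataFrame(
        [
            {"clade_id": c, "edge": e, "duplications": v[0], "losses": v[1]}
            for (c, e), v in sorted(log.items())
        ]
    )
    return SimulatedFamily(
        gene_trees=gene_trees,
        matrix=matrix,
        truth=truth,
        extinct=tuple(extinct),
        event_log=event_log,
        gene_table=gene_table,
        config=config,
    )


def write_family(family: SimulatedFamily, out_dir) -> dict:
    """Write a simulated family to ``out_dir``; returns the manifest.

    Emits one Newick file per surviving clade plus ``gene_species.tsv``,
    ``clades.tsv``, ``truth.tsv``, ``events_true.tsv`` and
    ``manifest.json`` (config, seed, file list) — all of which round-trip
    through the pipeline's readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for clade_id, tree in sorted(family.gene_trees.items()):
        name = f"gene_tree_{clade_id}.nwk"
        (out / name).write_text(tree.write_newick() + "\n")
        files.append(name)
    family.gene_table[["gene_id", "species_id", "pseudogene"]].to_csv(
        out / "gene_species.tsv", sep="\t", index=False
    )
    family.gene_table[["gene_id", "clade_id"]].to_csv(
        out / "clades.tsv", sep="\t", index=False
    )
    truth = pd.DataFrame(
        [
            {
                "clade_id": c,
                "true_class": cls,
                "extinct": int(c in family.extinct),
            }
            for c, cls in sorted(family.truth.items())
        ]
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    family.event_log.to_csv(out / "events_true.tsv", sep="\t", index=False)
    files += ["gene_species.tsv", "clades.tsv", "truth.tsv", "events_true.tsv"]
    manifest = {"config": family.config.to_jsonable(), "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_family(out_dir) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Reload the tabular outputs of :func:`write_family`."""
    out = Path(out_dir)
    gene_species = pd.read_csv(out / "gene_species.tsv", sep="\t")
    clades = pd.read_csv(out / "clades.tsv", sep="\t")
    manifest = json.loads((out / "manifest.json").read_text())
    return gene_species, clades, manifest
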