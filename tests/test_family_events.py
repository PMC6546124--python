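"""Copy-number matrices, stability calls, Dollo reconstruction, repertoires."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from bdfam.family_events import (
    CopyNumberMatrix,
    ancestral_counts,
    ancestral_repertoire,
    build_copy_matrix,
    classify_stability,
    dollo_reconstruct,
    ensure_node_labels,
    far_fixture_gene_table,
    lethality_proportions,
    repertoire_lower_bound,
)
from bdfam.treestats import parse_newick

from conftest import random_tree


def matrix_from(counts: dict, species, pseudo: dict | None = None) -> CopyNumberMatrix:
    clades = sorted(counts)
    c = pd.DataFrame(0, index=clades, columns=list(species), dtype=int)
    p = c.copy()
    for clade, row in counts.items():
        for sp, n in row.items():
            c.loc[clade, sp] = n
    for clade, row in (pseudo or {}).items():
        for sp, n in row.items():
            p.loc[clade, sp] = n
    return CopyNumberMatrix(counts=c, pseudo_counts=p)


class TestBuildCopyMatrix:
    def gene_tables(self):
        gs = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "species_id": ["sp1", "sp2", "sp1", "sp2"],
                "pseudogene": [0, 0, 0, 0],
            }
        )
        clades = {"g1": "c1", "g2": "c1", "g3": "c2", "g4": "c2"}
        return gs, clades

    def test_cross_tabulation(self):
        gs, clades = self.gene_tables()
        m = build_copy_matrix(gs, clades)
        assert (m.counts.values == 1).all()
        assert m.pseudo_counts.values.sum() == 0

    def test_pseudogene_flag_moves_count(self):
        gs, clades = self.gene_tables()
        gs.loc[0, "pseudogene"] = 1
        m = build_copy_matrix(gs, clades)
        assert m.counts.loc["c1", "sp1"] == 0
        assert m.pseudo_counts.loc["c1", "sp1"] == 1

    def test_orphan_gene_listed(self):
        gs, clades = self.gene_tables()
        del clades["g4"]
        with pytest.raises(ValueError, match="g4"):
            build_copy_matrix(gs, clades)

    def test_empty_clade_rejected(self):
        with pytest.raises(ValueError, match="no gene"):
            matrix_from({"c1": {"sp1": 1}, "c2": {}}, ["sp1"])


class TestClassifyStability:
    SPECIES = [f"sp{i}" for i in range(12)]

    def test_present_everywhere_is_stable(self):
        m = matrix_from({"c": {s: 1 for s in self.SPECIES}}, self.SPECIES)
        (call,) = classify_stability(m)
        assert call.status == "stable" and call.n_species_present == 12
        assert call.missing_species == ()

    def test_absence_makes_unstable_and_lists_missing(self):
        counts = {s: 1 for s in self.SPECIES}
        counts.pop("sp7")
        m = matrix_from({"c": counts}, self.SPECIES)
        (call,) = classify_stability(m)
        assert call.status == "unstable"
        assert call.missing_species == ("sp7",)

    def test_pseudogene_only_species_counts_as_missing_by_default(self):
        counts = {s: 1 for s in self.SPECIES if s != "sp3"}
        m = matrix_from({"c": counts}, self.SPECIES, pseudo={"c": {"sp3": 1}})
        (call,) = classify_stability(m)
        assert call.status == "unstable"
        (call,) = classify_stability(m, count_pseudogenes=True)
        assert call.status == "stable"

    def test_invariant_to_copy_number_magnitude(self, rng):
        counts = {
            f"c{i}": {s: int(rng.integers(0, 5)) for s in self.SPECIES}
            for i in range(6)
        }
        counts["c0"]["sp0"] = 1  # guard against an all-zero clade
        m = matrix_from(counts, self.SPECIES)
        capped = matrix_from(
            {c: {s: min(n, 1) for s, n in row.items()} for c, row in counts.items()},
            self.SPECIES,
        )
        assert [c.status for c in classify_stability(m)] == [
            c.status for c in classify_stability(capped)
        ]


def brute_min_losses(tree, present: set) -> int:
    """Exhaustive single-origin Dollo: minimum losses over all origins and
    loss-edge subsets whose implied tip pattern matches ``present``."""
    tips = list(tree.tip_labels)
    idx = {t: i for i, t in enumerate(tips)}
    masks = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = 1 << idx[node.taxon.label]
        else:
            masks[id(node)] = 0
            for c in node.child_nodes():
                masks[id(node)] |= masks[id(c)]
    pmask = 0
    for t in present:
        pmask |= 1 << idx[t]
    best = None
    for origin in tree.dendropy_tree.preorder_node_iter():
        om = masks[id(origin)]
        if om & pmask != pmask:
            continue
        target_absent = om & ~pmask
        below = [masks[id(n)] for n in origin.preorder_iter() if n is not origin]
        for size in range(0, len(below) + 1):
            if best is not None and size >= best:
                break
            hit = False
            for combo in combinations(below, size):
                u = 0
                for m in combo:
                    u |= m
                if u == target_absent:
                    hit = True
                    break
            if hit:
                best = size if best is None else min(best, size)
                break
    return best


class TestDolloReconstruct:
    def test_all_present_means_origin_at_root_no_losses(self, drosophila_tree):
        sp = list(drosophila_tree.tip_labels)
        m = matrix_from({"c": {s: 1 for s in sp}}, sp)
        (ev,) = dollo_reconstruct(m, drosophila_tree)
        assert ev.origin_node == "root" and ev.losses == ()
        assert all(ev.presence.values())

    def test_subgenus_restricted_clade_single_loss(self, far_fixture, drosophila_tree):
        # present in the whole subgenus Drosophila plus the willistoni group:
        # one loss after the willistoni divergence
        matrix, _ = far_fixture
        events = {e.clade_id: e for e in dollo_reconstruct(matrix, drosophila_tree)}
        ev = events["GJ13738"]
        assert ev.origin_node == "root"
        assert ev.losses == ("melobs",)

    def test_two_independent_terminal_losses(self, far_fixture, drosophila_tree):
        matrix, _ = far_fixture
        events = {e.clade_id: e for e in dollo_reconstruct(matrix, drosophila_tree)}
        assert events["CG14893"].losses == ("Dgri", "Dmoj")
        assert events["CG14893"].origin_node == "root"

    def test_pseudogene_presence_toggle(self, far_fixture, drosophila_tree):
        matrix, _ = far_fixture
        by_id = lambda evs: {e.clade_id: e for e in evs}
        default = by_id(dollo_reconstruct(matrix, drosophila_tree))
        with_pseudo = by_id(
            dollo_reconstruct(matrix, drosophila_tree, count_pseudogenes=True)
        )
        # the D. sechellia copy of CG10097 is a pseudogene: a loss by default,
        # presence when pseudogenes count
        assert default["CG10097"].losses == ("Dsec",)
        assert with_pseudo["CG10097"].losses == ()

    def test_origin_at_root_override_adds_losses(self, far_fixture, drosophila_tree):
        matrix, _ = far_fixture
        events = {
            e.clade_id: e
            for e in dollo_reconstruct(
                matrix, drosophila_tree, origin_at_root=["CG13091"]
            )
        }
        ev = events["CG13091"]
        assert ev.origin_node == "root"
        assert set(ev.losses) == {"Dana", "drosophila_subgenus"}

    def test_zero_presence_rejected(self, drosophila_tree):
        # clade "d" survives only as a pseudogene: no functional presence
        sp = list(drosophila_tree.tip_labels)
        m = matrix_from(
            {"c": {s: 1 for s in sp}, "d": {}}, sp, pseudo={"d": {"Dmel": 1}}
        )
        with pytest.raises(ValueError, match="zero presence"):
            dollo_reconstruct(m, drosophila_tree)

    def test_polytomy_children_each_get_a_loss(self):
        tree = ensure_node_labels(parse_newick("(A:1,B:1,C:1,D:1);"))
        m = matrix_from({"c": {"A": 1, "B": 0, "C": 0, "D": 1}}, ["A", "B", "C", "D"])
        (ev,) = dollo_reconstruct(m, tree)
        assert ev.losses == ("B", "C")

    def test_matches_exhaustive_enumeration_on_small_trees(self, rng):
        for n_tips in (3, 4, 5, 6):
            for _ in range(2):
                tree = ensure_node_labels(random_tree(rng, n_tips))
                tips = list(tree.tip_labels)
                for pattern in range(1, 2 ** n_tips):
                    present = {t for i, t in enumerate(tips) if pattern >> i & 1}
                    m = matrix_from(
                        {"c": {t: int(t in present) for t in tips}}, tips
                    )
                    (ev,) = dollo_reconstruct(m, tree)
                    assert ev.n_losses == brute_min_losses(tree, present), (
                        tree.write_newick(), sorted(present),
                    )

    def test_planted_losses_recovered(self, rng):
        # plant an origin and losses on maximal all-absent subtrees, then
        # reconstruct: parsimony recovers exactly those losses
        for _ in range(10):
            tree = ensure_node_labels(random_tree(rng, 8))
            internal = list(tree.dendropy_tree.preorder_internal_node_iter())
            origin = internal[int(rng.integers(0, len(internal)))]
            below = [n for n in origin.preorder_iter() if n is not origin]
            k = int(rng.integers(1, 3))
            below = [below[i] for i in rng.permutation(len(below))]
            losses, covered = [], set()
            for cand in below:
                leaves = tree.leaf_labels_below(cand)
                if leaves & covered:
                    continue
                if leaves == tree.leaf_labels_below(origin) - covered:
                    continue  # would erase all remaining presence
                losses.append(cand)
                covered |= leaves
                if len(losses) == k:
                    break
            present = tree.leaf_labels_below(origin) - covered
            if not present:
                continue
            tips = list(tree.tip_labels)
            m = matrix_from({"c": {t: int(t in present) for t in tips}}, tips)
            (ev,) = dollo_reconstruct(m, tree)
            assert ev.n_losses <= len(losses)


class TestAncestralRepertoire:
    def test_counts_at_root_and_below(self, drosophila_tree):
        sp = list(drosophila_tree.tip_labels)
        mel_only = {s: int(s in ("Dmel", "Dsim", "Dsec")) for s in sp}
        m = matrix_from(
            {"a": {s: 1 for s in sp}, "b": {s: 1 for s in sp}, "c": mel_only}, sp
        )
        events = dollo_reconstruct(m, drosophila_tree)
        assert ancestral_repertoire(events, "root") == 2
        assert ancestral_repertoire(events, "melsimsec") == 3
        with pytest.raises(KeyError):
            ancestral_repertoire(events, "nonexistent")

    def test_root_count_equals_root_origins(self, far_fixture, drosophila_tree):
        matrix, _ = far_fixture
        events = dollo_reconstruct(matrix, drosophila_tree)
        n_root_origins = sum(1 for e in events if e.origin_node == "root")
        assert ancestral_repertoire(events, "root") == n_root_origins

    def test_recount_oracle_on_simulated_patterns(self, rng, drosophila_tree):
        sp = list(drosophila_tree.tip_labels)
        counts = {}
        for i in range(8):
            row = {s: int(rng.random() < 0.7) for s in sp}
            if not any(row.values()):
                row[sp[0]] = 1
            counts[f"c{i}"] = row
        m = matrix_from(counts, sp)
        events = dollo_reconstruct(m, drosophila_tree)
        table = ancestral_counts(events, drosophila_tree)
        for _, row in table.iterrows():
            brute = sum(1 for e in events if e.presence[row["node_label"]])
            assert row["repertoire_size"] == brute


class TestRepertoireLowerBound:
    @pytest.mark.parametrize(
        "n, dups, expected", [(18, 3, 15), (7, 0, 7), (5, 5, 0)]
    )
    def test_arithmetic(self, n, dups, expected):
        assert repertoire_lower_bound(n, dups) == expected

    def test_negative_result_rejected(self):
        with pytest.raises(ValueError):
            repertoire_lower_bound(3, 4)


class TestFarFixture:
    def test_shape_and_species_match_tree(self, far_fixture, drosophila_tree):
        matrix, ann = far_fixture
        assert len(matrix.clades) == 18
        assert set(matrix.species) == set(drosophila_tree.tip_labels)
        assert int(ann["lineage_specific_duplicate"].sum()) == 3

    def test_stability_split(self, far_fixture):
        matrix, _ = far_fixture
        calls = classify_stability(matrix)
        assert sum(c.status == "stable" for c in calls) == 12
        assert sum(c.status == "unstable" for c in calls) == 6

    def test_sechellia_pseudogene_encoded(self, far_fixture):
        matrix, _ = far_fixture
        assert matrix.pseudo_counts.loc["CG10097", "Dsec"] == 1
        assert matrix.counts.loc["CG10097", "Dsec"] == 0

    def test_lethality_tally(self, far_fixture):
        matrix, ann = far_fixture
        calls = classify_stability(matrix)
        tally = lethality_proportions(ann, calls).set_index("status")
        assert tally.loc["stable", "n_tested"] == 12
        assert tally.loc["stable", "n_lethal"] == 9
        assert tally.loc["unstable", "n_tested"] == 5
        assert tally.loc["unstable", "n_lethal"] == 1

    def test_gene_table_roundtrips_to_matrix(self, far_fixture):
        matrix, _ = far_fixture
        genes = far_fixture_gene_table()
        rebuilt = build_copy_matrix(
            genes[["gene_id", "species_id", "pseudogene"]],
            dict(zip(genes["gene_id"], genes["clade_id"])),
        )
        assert rebuilt.counts.loc[matrix.clades, matrix.species].equals(matrix.counts)
        assert rebuilt.pseudo_counts.loc[matrix.clades, matrix.species].equals(
            matrix.pseudo_counts
        )
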