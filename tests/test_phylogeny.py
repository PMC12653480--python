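"""Substitution-model mechanics, ML distances against a dense grid-search
oracle, NJ exactness on additive matrices, and bootstrap support."""

import io

import dendropy
import numpy as np
import pytest

from orsite import (
    AlignedFamily,
    DistanceMatrix,
    SequenceRecord,
    ValidationError,
    bootstrap_support,
    distance_matrix,
    jtt_distance,
    nj_tree,
    write_newick,
)
from orsite.phylogeny import (
    UndefinedDistanceError,
    _pair_counts,
    pair_log_likelihood,
    read_newick,
)
from orsite.synthetic import random_tree


class TestModel:
    def test_transition_matrix_is_stochastic(self, model):
        for t in (0.0, 0.01, 0.5, 2.0, 10.0):
            p = model.transition_matrix(t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(p >= 0)
        assert np.allclose(model.transition_matrix(0.0), np.eye(20),
                           atol=1e-12)

    def test_stationarity_and_unit_rate(self, model):
        pi = model.frequencies
        p = model.transition_matrix(1.3)
        assert np.allclose(pi @ p, pi, atol=1e-12)
        assert -(pi * np.diag(model.rate_matrix)).sum() == pytest.approx(1.0)

    def test_detailed_balance(self, model):
        q = model.rate_matrix
        pi = model.frequencies
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)


def _simulate_pair(t, length, model, rng):
    """Draw an ancestral/descendant pair at divergence t."""
    anc = rng.choice(20, size=length, p=model.frequencies)
    p = model.transition_matrix(t)
    cum = np.cumsum(p, axis=1)
    u = rng.random(length)
    des = (u[:, None] > cum[anc, :]).sum(axis=1)
    a = "".join(model.alphabet[i] for i in anc)
    b = "".join(model.alphabet[i] for i in des)
    return a, b


class TestJttDistance:
    def test_identity_is_zero(self, model):
        a = "MKVLAWGHIPRSTNEQDYCF" * 5
        d, sat = jtt_distance(a, a, model)
        assert d == 0.0 and not sat

    def test_symmetry(self, model):
        rng = np.random.default_rng(0)
        a, b = _simulate_pair(0.5, 150, model, rng)
        dab, _ = jtt_distance(a, b, model)
        dba, _ = jtt_distance(b, a, model)
        assert dab == pytest.approx(dba, abs=1e-6)

    def test_matches_dense_grid_search(self, model):
        rng = np.random.default_rng(42)
        a, b = _simulate_pair(0.3, 200, model, rng)
        d, sat = jtt_distance(a, b, model)
        assert not sat
        counts = _pair_counts(a, b, model)
        # independent oracle: dense grid over the whole domain, step 1e-4
        grid = np.arange(0.0, 10.0 + 1e-4, 1e-4)
        best_t, best_ll = 0.0, -np.inf
        for chunk in np.array_split(grid, 100):
            ps = model.transition_matrices(chunk)
            with np.errstate(divide="ignore"):
                ll = np.einsum(
                    "ab,tab->t",
                    counts,
                    np.log(model.frequencies[None, :, None] * ps),
                )
            k = int(np.argmax(ll))
            if ll[k] > best_ll:
                best_ll, best_t = float(ll[k]), float(chunk[k])
        assert d == pytest.approx(best_t, abs=1e-3)

    def test_monotone_in_simulated_divergence(self, model):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(1)
        ts = np.linspace(0.05, 2.3, 10)
        estimates = []
        for t in ts:
            a, b = _simulate_pair(t, 1000, model, rng)
            estimates.append(jtt_distance(a, b, model)[0])
        rho = spearmanr(ts, estimates).statistic
        assert rho > 0.95

    def test_no_shared_columns_is_undefined(self, model):
        with pytest.raises(UndefinedDistanceError):
            jtt_distance("MK--", "--AL", model)

    def test_frozen_dist_ml_oracle(self, model):
        """Distances agree with an independently computed reference.

        The expected matrix was computed once for this exact simulated
        family with R phangorn's dist.ml under the same model and frozen.
        """
        from orsite import FamilySimSpec, simulate_family

        fam, _ = simulate_family(
            FamilySimSpec(
                n_taxa=4, length=300, fraction_invariant=0.1,
                fraction_fast=0.3, rate_multipliers=(0.0, 1.0, 2.2),
                edge_length_mean=0.2, max_terminal_trim=5, seed=7,
            )
        )
        dm = distance_matrix(fam, model)
        assert dm.labels == ("focal", "sp04", "sp01", "sp02")
        expected = np.array(
            [
                [0.0, 0.4705762, 0.4184006, 0.4685387],
                [0.4705762, 0.0, 0.3618350, 0.4486383],
                [0.4184006, 0.3618350, 0.0, 0.4014718],
                [0.4685387, 0.4486383, 0.4014718, 0.0],
            ]
        )
        assert np.allclose(dm.values, expected, atol=2e-4)


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, sim_family, model):
        dm = distance_matrix(sim_family, model)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert dm.mean_pairwise() > 0

    def test_identical_members_distance_zero(self, model):
        fam = AlignedFamily(
            members=(
                SequenceRecord("a", "MKVLAWGHIP"),
                SequenceRecord("b", "MKVLAWGHIP"),
            ),
            reference_id="a",
        )
        assert distance_matrix(fam, model).get("a", "b") == 0.0

    def test_simulated_tree_distances_track_path_lengths(self, model):
        # 4-taxon tree with known path lengths, long alignment
        newick = "((a:0.15,b:0.25):0.1,(c:0.2,d:0.1):0.1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        from orsite import FamilySimSpec, simulate_family

        fam, _ = simulate_family(
            FamilySimSpec(
                n_taxa=4, length=2000, tree=tree, fraction_invariant=0.0,
                fraction_fast=0.0, rate_multipliers=(0.0, 1.0, 2.0),
                max_terminal_trim=0, seed=5,
            )
        )
        dm = distance_matrix(fam, model)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        ids = [m.id for m in fam.members]
        relabel = dict(zip(["focal"] + ids[1:], ["a"] + ids[1:]))
        for i, x in enumerate(ids):
            for y in ids[i + 1:]:
                truth = pdm.patristic_distance(
                    taxa[relabel[x]], taxa[relabel[y]]
                )
                assert dm.get(x, y) == pytest.approx(truth, rel=0.10)


def _additive_matrix_from_tree(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(
                taxa[i], taxa[j]
            )
    return DistanceMatrix(labels, values)


def _bipartitions(tree):
    tree.encode_bipartitions()
    return {
        e.bipartition.split_bitmask
        for e in tree.preorder_edge_iter()
        if e.bipartition is not None and not e.bipartition.is_trivial()
    }


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
        )
        tree = nj_tree(dm)
        assert tree.branch_length("A") == pytest.approx(1.0)
        assert tree.branch_length("B") == pytest.approx(1.0)
        assert tree.branch_length("C") == pytest.approx(3.0)

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float))
        tree = nj_tree(dm)
        text = write_newick(tree)
        assert text.startswith("(") and "A:0.5" in text and "B:0.5" in text

    def test_single_taxon_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(("A",), np.zeros((1, 1))))

    def test_four_taxon_additive_exact_branch_lengths(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> additive distances
        newick = "((a:1,b:2):3,(c:4,d:5):0);"
        src = dendropy.Tree.get(data=newick, schema="newick")
        dm = _additive_matrix_from_tree(src)
        out = nj_tree(dm)
        for leaf, expected in zip("abcd", (1, 2, 4, 5)):
            assert out.branch_length(leaf) == pytest.approx(expected)
        # the single internal edge carries the full 3.0
        internal = [
            e.length
            for e in out.tree.preorder_edge_iter()
            if e.head_node and not e.head_node.is_leaf()
            and e.length is not None
        ]
        assert pytest.approx(3.0) in internal

    @pytest.mark.parametrize("n_taxa", range(4, 13))
    def test_additive_matrices_recover_topology(self, n_taxa):
        """NJ is exact on additive matrices (12 random trees per size)."""
        for rep in range(12):
            rng = np.random.default_rng(1000 * n_taxa + rep)
            src = random_tree(n_taxa, rng, edge_length_mean=0.3)
            for edge in src.preorder_edge_iter():  # keep it strictly additive
                if edge.length is not None:
                    edge.length = float(edge.length) + 0.05
            dm = _additive_matrix_from_tree(src)
            out = nj_tree(dm, taxon_namespace=src.taxon_namespace)
            assert _bipartitions(out.tree) == _bipartitions(src)

    def test_agrees_with_dendropy_nj(self):
        """Independent-implementation cross-check on a noisy matrix."""
        rng = np.random.default_rng(8)
        src = random_tree(7, rng, edge_length_mean=0.4)
        dm = _additive_matrix_from_tree(src)
        noisy = dm.values + rng.uniform(0, 0.01, dm.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm_noisy = DistanceMatrix(dm.labels, noisy)
        mine = nj_tree(dm_noisy)
        csv = ",".join(("",) + dm.labels) + "\n" + "\n".join(
            ",".join([lab] + [f"{x:.8f}" for x in noisy[i]])
            for i, lab in enumerate(dm.labels)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=","
        )
        theirs = pdm.nj_tree()
        # same bipartitions, compared via label sets
        def label_splits(t):
            t.encode_bipartitions()
            all_labels = frozenset(
                lf.taxon.label for lf in t.leaf_node_iter()
            )
            out = set()
            for e in t.preorder_edge_iter():
                if e.bipartition is None or e.bipartition.is_trivial():
                    continue
                side = frozenset(
                    lf.taxon.label
                    for lf in e.head_node.leaf_iter()
                )
                out.add(min(side, all_labels - side, key=sorted))
            return out

        assert label_splits(mine.tree) == label_splits(theirs)


class TestBootstrap:
    def _clade_family(self):
        # one informative column repeated: (a,b)=A, (c,d)=L, e=S
        col = dict(a="A", b="A", c="L", d="L", e="S")
        members = tuple(
            SequenceRecord(k, v * 60) for k, v in col.items()
        )
        return AlignedFamily(members=members, reference_id="a")

    def test_unanimous_support_is_100(self, model):
        fam = self._clade_family()
        tree = bootstrap_support(fam, model, replicates=100, seed=3)
        assert tree.support  # has internal bipartitions
        assert all(v == pytest.approx(100.0) for v in tree.support.values())

    def test_same_seed_reproduces_support(self, sim_family, model):
        t1 = bootstrap_support(sim_family, model, replicates=20, seed=9)
        t2 = bootstrap_support(sim_family, model, replicates=20, seed=9)
        assert t1.support == t2.support

    def test_support_fraction_formula(self, sim_family, model):
        tree = bootstrap_support(sim_family, model, replicates=25, seed=4)
        for v in tree.support.values():
            assert 0.0 <= v <= 100.0
            # with 25 kept replicates every support is a multiple of 4
            assert v * 25 / 100 == pytest.approx(round(v * 25 / 100))


class TestNewick:
    def test_round_trip_preserves_bipartitions_and_lengths(self, model,
                                                           sim_family):
        dm = distance_matrix(sim_family, model)
        tree = nj_tree(dm)
        text = write_newick(tree)
        back = read_newick(text)
        assert {lf for lf in back.leaf_labels()} == tree.leaf_labels()

        def split_lengths(t):
            out = {}
            all_labels = frozenset(lf for lf in t.leaf_labels())
            for e in t.tree.preorder_edge_iter():
                if e.head_node is t.tree.seed_node:
                    continue
                side = frozenset(
                    lf.taxon.label for lf in e.head_node.leaf_iter()
                )
                key = min(side, all_labels - side, key=sorted)
                out[key] = float(e.length or 0.0)
            return out

        a, b = split_lengths(tree), split_lengths(back)
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_outgroup_rooting_keeps_bipartitions(self, model, sim_family):
        dm = distance_matrix(sim_family, model)
        tree = nj_tree(dm)
        before = tree.bipartitions()
        out_label = sorted(tree.leaf_labels())[0]
        text = write_newick(tree, outgroup=out_label)
        back = read_newick(text)

        def label_bips(t):
            all_labels = frozenset(t.leaf_labels())
            t.tree.encode_bipartitions()
            out = set()
            for e in t.tree.preorder_edge_iter():
                if e.bipartition is None or e.bipartition.is_trivial():
                    continue
                side = frozenset(
                    lf.taxon.label for lf in e.head_node.leaf_iter()
                )
                out.add(min(side, all_labels - side, key=sorted))
            return out

        assert label_bips(back) == label_bips(
            read_newick(write_newick(tree))
        )
        assert tree.bipartitions() == before  # original untouched

    def test_unknown_outgroup_rejected(self, model, sim_family):
        tree = nj_tree(distance_matrix(sim_family, model))
        with pytest.raises(ValidationError):
            write_newick(tree, outgroup="not-a-taxon")
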