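import numpy as np
import pytest

from barcodekit.distances import distance_matrix
from barcodekit.library_io import LibraryError
from barcodekit.phylogeny import (
    bipartitions,
    bootstrap_support,
    flag_taxonomic_outliers,
    neighbor_joining,
    robinson_foulds,
    sum_branch_lengths,
    write_newick,
)
from barcodekit.synthetic_data import SimulationParams, simulate_library

from conftest import make_library, matrix_from_array


def random_additive_tree(rng, n_leaves, with_outgroup=False):
    """Independent oracle: random binary tree -> induced leaf distances.

    Builds a tree by random joins with branch lengths in [0.05, 1.0], tracking
    leaf-to-subtree-root depths, all pairwise path lengths, and every clade
    created. Returns (leaf names, distance matrix, non-trivial bipartitions).
    """
    names = [f"L{i:02d}" for i in range(n_leaves)]
    if with_outgroup:
        names = names + ["OUT"]
    # each active subtree: (set of leaves, {leaf: depth to subtree root})
    active = [({nm}, {nm: 0.0}) for nm in names[: n_leaves if with_outgroup else len(names)]]
    pairs: dict[frozenset, float] = {}
    clades: list[set] = []

    def join(a, b, la, lb):
        leaves_a, depth_a = a
        leaves_b, depth_b = b
        for x in leaves_a:
            for y in leaves_b:
                pairs[frozenset((x, y))] = depth_a[x] + la + depth_b[y] + lb
        merged = leaves_a | leaves_b
        depths = {x: d + la for x, d in depth_a.items()}
        depths.update({y: d + lb for y, d in depth_b.items()})
        clades.append(merged)
        return (merged, depths)

    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        active.append(join(a, b, rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)))
    if with_outgroup:
        active.append(({"OUT"}, {"OUT": 0.0}))
        b = active.pop()
        a = active.pop()
        active.append(join(a, b, rng.uniform(0.05, 1.0), rng.uniform(2.0, 3.0)))

    all_leaves = frozenset(names)
    parts = set()
    for clade in clades:
        side, other = frozenset(clade), all_leaves - frozenset(clade)
        if len(side) >= 2 and len(other) >= 2:
            parts.add(frozenset((side, other)))
    d = np.zeros((len(names), len(names)))
    for i, x in enumerate(names):
        for j, y in enumerate(names):
            if i != j:
                d[i, j] = pairs[frozenset((x, y))]
    return names, d, parts


class TestNeighborJoining:
    def test_four_taxon_additive_matrix(self):
        # d(A,B)=d(C,D)=0.2, cross pairs 0.3: AB|CD with all edges 0.1
        d = np.array(
            [
                [0.0, 0.2, 0.3, 0.3],
                [0.2, 0.0, 0.3, 0.3],
                [0.3, 0.3, 0.0, 0.2],
                [0.3, 0.3, 0.2, 0.0],
            ]
        )
        dm = matrix_from_array(d, ids=list("ABCD"))
        tree = neighbor_joining(dm)
        parts = bipartitions(tree)
        assert parts == {frozenset((frozenset("AB"), frozenset("CD")))}
        assert sum_branch_lengths(tree) == pytest.approx(0.5, abs=1e-12)
        tt = tree.tip_tip_distances()
        assert tt[("A", "B")] == pytest.approx(0.2, abs=1e-12)
        assert tt[("A", "C")] == pytest.approx(0.3, abs=1e-12)

    def test_three_taxon_star_closed_form(self):
        d = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]])
        tree = neighbor_joining(matrix_from_array(d, ids=list("ABC")))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.5 * (0.3 + 0.4 - 0.5))
        assert lengths["B"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.4))
        assert lengths["C"] == pytest.approx(0.5 * (0.4 + 0.5 - 0.3))

    def test_small_matrix_rejected(self):
        with pytest.raises(LibraryError):
            neighbor_joining(matrix_from_array(np.zeros((2, 2)), ids=["a", "b"]))

    def test_undefined_pairs_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(LibraryError, match="undefined"):
            neighbor_joining(matrix_from_array(d))

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_exact_on_random_additive_matrices(self, rng, n_leaves):
        for _ in range(10):
            names, d, true_parts = random_additive_tree(rng, n_leaves)
            tree = neighbor_joining(matrix_from_array(d, ids=names))
            assert bipartitions(tree) == true_parts
            tt = tree.tip_tip_distances()
            for i, x in enumerate(names):
                for y in names[i + 1 :]:
                    assert abs(tt[(x, y)] - d[names.index(x), names.index(y)]) <= 1e-9

    def test_agrees_with_skbio_nj_on_additive_matrices(self, rng):
        """Independent implementation cross-check on recoverable inputs."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            names, d, _ = random_additive_tree(rng, 7)
            mine = neighbor_joining(matrix_from_array(d, ids=names))
            theirs = skbio_nj(SkDM(d, ids=names))
            assert robinson_foulds(mine, theirs) == 0

    def test_outgroup_only_roots_the_display(self, rng):
        """Removing a distant outgroup leaves the ingroup topology unchanged."""
        for _ in range(5):
            names, d, _ = random_additive_tree(rng, 6, with_outgroup=True)
            ingroup = names[:-1]
            full = neighbor_joining(matrix_from_array(d, ids=names))
            sub = d[np.ix_(range(6), range(6))]
            alone = neighbor_joining(matrix_from_array(sub, ids=ingroup))
            ing = frozenset(ingroup)
            restricted = set()
            for part in bipartitions(full):
                a, b = (frozenset(s & ing) for s in part)
                if len(a) >= 2 and len(b) >= 2:
                    restricted.add(frozenset((a, b)))
            assert restricted == bipartitions(alone)

    def test_clamp_negative_transfers_to_sister(self):
        # strongly non-additive matrix that produces a negative NJ limb
        d = np.array(
            [
                [0.0, 0.1, 0.1, 0.4],
                [0.1, 0.0, 0.1, 0.4],
                [0.1, 0.1, 0.0, 0.1],
                [0.4, 0.4, 0.1, 0.0],
            ]
        )
        dm = matrix_from_array(d, ids=list("ABCD"))
        plain = neighbor_joining(dm)
        clamped = neighbor_joining(dm, clamp_negative=True)
        assert min(n.length for n in clamped.traverse(include_self=False)) >= 0.0
        assert sum_branch_lengths(clamped) == pytest.approx(sum_branch_lengths(plain))


class TestSumBranchLengths:
    def test_all_zero_lengths(self):
        lib = make_library({"a1": "ACGT", "a2": "ACGT", "a3": "ACGT"})
        tree = neighbor_joining(distance_matrix(lib))
        assert sum_branch_lengths(tree) == 0.0


class TestBootstrap:
    def _separated_library(self):
        rng = np.random.default_rng(11)
        base1 = "".join(rng.choice(list("ACGT"), size=120))
        flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
        # second cluster: ~30% divergence, well below JC saturation
        b2 = list(base1)
        for pos in rng.choice(120, size=36, replace=False):
            b2[pos] = flip[b2[pos]]
        base2 = "".join(b2)
        def mutate(seq, sites):
            s = list(seq)
            for pos in sites:
                s[pos] = flip[s[pos]]
            return "".join(s)

        # sister species differ at 12 sites so no column resample erases them
        near1 = mutate(base1, range(0, 24, 2))
        near2 = mutate(base2, range(1, 24, 2))
        seqs = {
            "a1": base1, "a2": base1,  # species a
            "b1": near1, "b2": near1,  # species b, close to a
            "c1": base2, "c2": base2,  # species c
            "d1": near2, "d2": near2,  # species d, close to c
        }
        return make_library(seqs)

    def test_separated_clusters_have_full_support(self):
        # two 2-species clusters: the cluster split is the only internal edge
        lib = self._separated_library()
        lib = lib.subset(["a1", "b1", "c1", "d1"])
        tree, n_skipped = bootstrap_support(lib, model="JC", n_reps=100, seed=3)
        assert n_skipped == 0
        all_tips = frozenset(lib.ids)
        supports = {}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            supports[frozenset((side, all_tips - side))] = float(node.name)
        split = frozenset((frozenset(["a1", "b1"]), frozenset(["c1", "d1"])))
        assert supports == {split: 1.0}

    def test_separating_edge_full_support_with_individuals(self):
        # 2 individuals per species: the between-cluster edge is still certain
        lib = self._separated_library()
        tree, n_skipped = bootstrap_support(lib, model="JC", n_reps=100, seed=3)
        assert n_skipped == 0
        all_tips = frozenset(lib.ids)
        supports = {}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            supports[frozenset((side, all_tips - side))] = float(node.name)
        ab_cd = frozenset(
            (frozenset(["a1", "a2", "b1", "b2"]), frozenset(["c1", "c2", "d1", "d2"]))
        )
        assert supports[ab_cd] == 1.0

    def test_seeded_run_is_deterministic(self):
        lib = self._separated_library()
        import io

        outs = []
        for _ in range(2):
            tree, _ = bootstrap_support(lib, n_reps=5, seed=42)
            buf = io.StringIO()
            write_newick(tree, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_support_in_unit_interval_and_leaf_order_invariant(self):
        lib, _ = simulate_library(
            SimulationParams(
                n_families=2, genera_per_family=2, species_per_genus=1,
                individuals_per_species=3, singleton_fraction=0.0,
                d_family=0.12, d_genus=0.06, d_species=0.03, d_intra=0.01,
                seq_length=600, seed=5,
            )
        )
        shuffled = type(lib)(
            marker=lib.marker, records=list(reversed(lib.records)), aligned=True
        )

        def support_map(library):
            tree, _ = bootstrap_support(library, n_reps=30, seed=9)
            tips = frozenset(library.ids)
            out = {}
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                out[frozenset((side, tips - side))] = float(node.name)
            return out

        s1, s2 = support_map(lib), support_map(shuffled)
        assert all(0.0 <= v <= 1.0 for v in s1.values())
        assert s1 == s2


class TestOutlierFlagging:
    def _three_family_matrix(self):
        # P4 carries the Poaceae label but sits inside the Fabaceae cluster
        ids = ["P1", "P2", "P3", "F1", "F2", "F3", "P4", "A1", "A2", "A3"]
        labels = {
            "P1": "Poaceae", "P2": "Poaceae", "P3": "Poaceae", "P4": "Poaceae",
            "F1": "Fabaceae", "F2": "Fabaceae", "F3": "Fabaceae",
            "A1": "Asteraceae", "A2": "Asteraceae", "A3": "Asteraceae",
        }
        cluster = {"P1": 0, "P2": 0, "P3": 0, "F1": 1, "F2": 1, "F3": 1,
                   "P4": 1, "A1": 2, "A2": 2, "A3": 2}
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = cluster[ids[i]] == cluster[ids[j]]
                d[i, j] = d[j, i] = 0.02 + 0.001 * (i + j) if same else 0.4
        return matrix_from_array(d, ids=ids), labels

    def test_constructed_outlier_is_flagged(self):
        dm, labels = self._three_family_matrix()
        tree = neighbor_joining(dm)
        flags, skipped = flag_taxonomic_outliers(tree, labels, k=3)
        assert [f.record_id for f in flags] == ["P4"]
        assert set(flags[0].neighbour_labels) == {"Fabaceae"}
        assert not skipped

    def test_monophyletic_tree_yields_no_flags(self):
        dm, labels = self._three_family_matrix()
        labels = dict(labels, P4="Fabaceae")  # fix the label: clusters now clean
        tree = neighbor_joining(dm)
        flags, _ = flag_taxonomic_outliers(tree, labels, k=3)
        assert flags == []

    def test_single_member_rank_skipped(self):
        dm, labels = self._three_family_matrix()
        labels = dict(labels, A1="Malvaceae")
        tree = neighbor_joining(dm)
        flags, skipped = flag_taxonomic_outliers(tree, labels, k=3)
        assert "A1" in skipped

    def test_bad_k_rejected(self):
        dm, labels = self._three_family_matrix()
        with pytest.raises(LibraryError):
            flag_taxonomic_outliers(neighbor_joining(dm), labels, k=0)
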