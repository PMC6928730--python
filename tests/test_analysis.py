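"""Clustering, 2-D projection, and length-width / amino-acid profiles."""

import warnings

import numpy as np
import pytest
from sklearn.cluster import KMeans, kmeans_plusplus
from sklearn.metrics import adjusted_rand_score

from cavity2vec import (
    TrainConfig,
    amino_acid_profile,
    embed_corpus,
    generate_trajectories,
    hierarchical_cluster,
    kmeans_cluster,
    length_width_profile,
    project_2d,
    train,
)
from cavity2vec.analysis import ClusterAssignment
from cavity2vec.structures import Atom, CavityNode, CavitySequence


# ---------------------------------------------------------------------------
# Independent O(n^3) average-link oracle
# ---------------------------------------------------------------------------

def brute_force_average_link_heights(X: np.ndarray) -> list[float]:
    """Naive agglomerative average linkage on cosine distance: at every
    step merge the pair of clusters with the smallest mean pairwise
    distance; return the merge heights in order."""
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / norms
    D = 1.0 - Xn @ Xn.T
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(X))}
    heights = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestHierarchical:
    def test_forced_geometry_two_clusters(self):
        vecs = {"a": np.array([1.0, 0.0]), "b": np.array([1.0, 1e-9]),
                "c": np.array([-1.0, 0.0])}
        asg = hierarchical_cluster(vecs, n_clusters=2)
        assert asg.assignments["a"] == asg.assignments["b"] != asg.assignments["c"]

    @pytest.mark.parametrize("n", [4, 12])
    def test_merge_heights_match_brute_force(self, rng, n):
        X = rng.normal(size=(n, 5))
        vecs = {f"c{i}": X[i] for i in range(n)}
        asg = hierarchical_cluster(vecs, n_clusters=2)
        got = np.sort(asg.linkage_matrix[:, 2])
        expected = np.sort(brute_force_average_link_heights(X))
        assert np.allclose(got, expected, atol=1e-10)

    def test_threshold_cut_may_give_one_cluster(self, rng):
        X = rng.normal(size=(6, 4))
        asg = hierarchical_cluster({f"c{i}": X[i] for i in range(6)},
                                   distance_threshold=10.0)
        assert asg.n_clusters == 1

    def test_exactly_one_cut_criterion(self, rng):
        vecs = {f"c{i}": rng.normal(size=3) for i in range(4)}
        with pytest.raises(ValueError):
            hierarchical_cluster(vecs)
        with pytest.raises(ValueError):
            hierarchical_cluster(vecs, n_clusters=2, distance_threshold=0.5)

    def test_invalid_linkage_rejected(self, rng):
        vecs = {f"c{i}": rng.normal(size=3) for i in range(4)}
        with pytest.raises(ValueError, match="linkage"):
            hierarchical_cluster(vecs, n_clusters=2, linkage_method="ward")

    def test_recovers_planted_templates(self):
        """Low-noise 3-template data: cutting the dendrogram at k=3
        recovers the planted labels (median ARI over 10 seeds >= 0.9)."""
        aris = []
        for seed in range(10):
            ds = generate_trajectories(k_templates=3, n_per_template=8,
                                       node_dropout_prob=0.1, node_swap_prob=0.05,
                                       seed=seed, n_atoms=200, length_range=(8, 14))
            model = train(ds.corpus(), TrainConfig(dimension=16, window=2,
                                                   negative=5, epochs=20, seed=seed))
            vecs = embed_corpus(ds.sequences, model)
            asg = hierarchical_cluster(vecs, n_clusters=3)
            ids = [v.cavity_id for v in vecs]
            aris.append(adjusted_rand_score([ds.labels[i] for i in ids],
                                            asg.labels_for(ids)))
        assert np.median(aris) >= 0.9


class TestKMeans:
    def test_k_equals_n_gives_singletons(self, rng):
        vecs = {f"c{i}": rng.normal(size=4) for i in range(5)}
        asg = kmeans_cluster(vecs, k=5, seed=0)
        assert asg.n_clusters == 5
        assert asg.inertia == pytest.approx(0.0, abs=1e-12)

    def test_separated_blobs_split_perfectly(self, rng):
        X = np.vstack([rng.normal([5, 0, 0], 0.05, (10, 3)),
                       rng.normal([-5, 0, 0], 0.05, (10, 3))])
        vecs = {f"c{i}": X[i] for i in range(20)}
        asg = kmeans_cluster(vecs, k=2, seed=1)
        labels = asg.labels_for([f"c{i}" for i in range(20)])
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_out_of_range_rejected(self, rng):
        vecs = {f"c{i}": rng.normal(size=3) for i in range(4)}
        with pytest.raises(ValueError):
            kmeans_cluster(vecs, k=5)
        with pytest.raises(ValueError):
            kmeans_cluster(vecs, k=1)

    def test_lloyd_inertia_never_increases(self, rng):
        """Stepping Lloyd's algorithm one iteration at a time from a
        k-means++ start: the inertia sequence is non-increasing."""
        X = rng.normal(size=(40, 6))
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        centers, _ = kmeans_plusplus(Xn, n_clusters=4, random_state=0)
        inertias = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(8):
                km = KMeans(n_clusters=4, init=centers, n_init=1, max_iter=1,
                            algorithm="lloyd").fit(Xn)
                inertias.append(km.inertia_)
                centers = km.cluster_centers_
        assert all(b <= a + 1e-10 for a, b in zip(inertias, inertias[1:]))

    def test_restarts_never_worsen_inertia(self, rng):
        X = rng.normal(size=(30, 4))
        vecs = {f"c{i}": X[i] for i in range(30)}
        one = kmeans_cluster(vecs, k=3, seed=5, n_init=1)
        many = kmeans_cluster(vecs, k=3, seed=5, n_init=10)
        assert many.inertia <= one.inertia + 1e-10


class TestProjection:
    def test_shape_and_determinism(self, rng):
        vecs = {f"c{i}": rng.normal(size=8) for i in range(40)}
        a = project_2d(vecs, perplexity=5, seed=3)
        b = project_2d(vecs, perplexity=5, seed=3)
        assert set(a) == set(vecs)
        assert all(np.isfinite(xy).all() and len(xy) == 2 for xy in a.values())
        assert a == b

    def test_perplexity_too_large_rejected(self, rng):
        vecs = {f"c{i}": rng.normal(size=4) for i in range(10)}
        with pytest.raises(ValueError, match="perplexity"):
            project_2d(vecs, perplexity=5, seed=0)

    def test_templates_stay_local_in_projection(self, clean_dataset, clean_model):
        vecs = embed_corpus(clean_dataset.sequences, clean_model)
        coords = project_2d(vecs, perplexity=5, seed=0)
        ids = list(coords)
        P = np.array([coords[i] for i in ids])
        labels = np.array([clean_dataset.labels[i] for i in ids])
        D = np.linalg.norm(P[:, None] - P[None], axis=2)
        same = labels[:, None] == labels[None]
        off = ~np.eye(len(ids), dtype=bool)
        assert D[same & off].mean() < D[~same].mean()


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _node(serials, center, radius):
    return CavityNode(node_id=".".join(str(s) for s in sorted(serials)),
                      center=np.asarray(center, float), radius=radius,
                      lining_atom_serials=tuple(serials))


def _atom(serial, res_name="ALA", res_seq=1, chain="A"):
    return Atom(serial=serial, name="C1", element="C", res_name=res_name,
                res_seq=res_seq, chain=chain, position=np.zeros(3), vdw_radius=1.7)


class TestLengthWidthProfile:
    def test_single_node(self):
        seq = CavitySequence("c0", 0, [_node((1, 2, 3, 4), (0, 0, 0), 1.5)])
        prof = length_width_profile(seq)
        assert prof.samples == [(0.0, 1.5)] and prof.bottleneck_radius == 1.5

    def test_collinear_hand_geometry(self):
        nodes = [_node((1, 2, 3, 4), (i, 0, 0), r)
                 for i, r in enumerate([2.0, 1.0, 2.0])]
        prof = length_width_profile(CavitySequence("c0", 0, nodes))
        assert np.allclose(prof.arc_lengths, [0, 1, 2])
        assert prof.bottleneck_index == 1 and prof.bottleneck_radius == 1.0

    def test_arc_lengths_non_decreasing(self, noisy_dataset):
        for seq in noisy_dataset.sequences:
            prof = length_width_profile(seq)
            assert prof.arc_lengths[0] == 0.0
            assert np.all(np.diff(prof.arc_lengths) >= 0)

    def test_zero_noise_profile_reproduces_generator(self, clean_dataset):
        for seq in clean_dataset.sequences[:5]:
            tmpl = clean_dataset.templates[clean_dataset.labels[seq.cavity_id]]
            prof = length_width_profile(seq)
            assert np.array_equal(prof.radii, tmpl.base_radius_profile)
            expected_arc = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(tmpl.waypoints, axis=0),
                                                 axis=1))])
            assert np.allclose(prof.arc_lengths, expected_arc)


class TestAminoAcidProfile:
    def test_single_residue_counts_once(self):
        atoms = [_atom(s, "ALA", 1) for s in (1, 2, 3, 4)]
        seq = CavitySequence("c0", 0, [_node((1, 2, 3, 4), (0, 0, 0), 1.0)])
        (prof,) = amino_acid_profile([seq], atoms)
        assert prof.counts == {"ALA": 1.0}

    def test_cluster_mean_is_hand_average(self):
        atoms = ([_atom(s, "ALA", rs) for rs, block in enumerate(
            [(1, 2, 3, 4), (5, 6, 7, 8), (9, 10, 11, 12)], start=1)
            for s in block])
        seq_a = CavitySequence("a", 0, [_node((1, 2, 3, 4), (0, 0, 0), 1.0)])
        seq_b = CavitySequence("b", 0, [
            _node((1, 2, 3, 4), (0, 0, 0), 1.0),
            _node((5, 6, 7, 8), (1, 0, 0), 1.0),
            _node((9, 10, 11, 12), (2, 0, 0), 1.0),
        ])
        asg = ClusterAssignment(assignments={"a": 0, "b": 0}, method="kmeans",
                                parameters={}, n_clusters=1)
        (prof,) = amino_acid_profile([seq_a, seq_b], atoms, assignment=asg)
        assert prof.unit == "cluster:0"
        assert prof.counts == {"ALA": 2.0}  # mean of 1 and 3 distinct residues

    def test_hid_kept_distinct_from_his(self):
        atoms = [_atom(s, "HIS", 1) for s in (1, 2, 3, 4)] + \
                [_atom(s, "HID", 2) for s in (5, 6, 7, 8)]
        seq = CavitySequence("c0", 0, [_node((1, 2, 3, 4), (0, 0, 0), 1.0),
                                       _node((5, 6, 7, 8), (1, 0, 0), 1.0)])
        (prof,) = amino_acid_profile([seq], atoms)
        assert prof.counts == {"HIS": 1.0, "HID": 1.0}

    def test_unknown_serial_is_named(self):
        atoms = [_atom(s) for s in (1, 2, 3, 4)]
        seq = CavitySequence("c0", 0, [_node((1, 2, 3, 99), (0, 0, 0), 1.0)])
        with pytest.raises(KeyError, match="99"):
            amino_acid_profile([seq], atoms)

    def test_invariant_to_node_order(self, noisy_dataset):
        seq = noisy_dataset.sequences[0]
        if len(seq) < 2:
            pytest.skip("needs a multi-node sequence")
        reversed_seq = CavitySequence(seq.cavity_id, seq.snapshot,
                                      list(reversed(seq.nodes)))
        (a,) = amino_acid_profile([seq], noisy_dataset.atoms)
        (b,) = amino_acid_profile([reversed_seq], noisy_dataset.atoms)
        assert a.counts == b.counts

    def test_matches_residue_set_oracle(self, noisy_dataset):
        atom_by_serial = {a.serial: a for a in noisy_dataset.atoms}
        profs = amino_acid_profile(noisy_dataset.sequences, noisy_dataset.atoms)
        by_unit = {p.unit: p.counts for p in profs}
        for seq in noisy_dataset.sequences[:10]:
            residues = {atom_by_serial[s].residue_key
                        for n in seq.nodes for s in n.lining_atom_serials}
            expected: dict[str, float] = {}
            for key in residues:
                # find the residue name from any atom of that residue
                name = next(a.res_name for a in noisy_dataset.atoms
                            if a.residue_key == key)
                expected[name] = expected.get(name, 0.0) + 1.0
            assert by_unit[seq.cavity_id] == expected
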