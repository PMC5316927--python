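"""Event-tree parsing, path-sum systems, solving and dating."""

import numpy as np
import pytest

from wgdkit import chronology as chron
from wgdkit import simulate

TWO_TIP = "((A,B)split)root:type=wgd;"


def two_tip_tree():
    return chron.EventTree.from_newick("(A,B)root:type=wgd;")


class TestEventTree:
    def test_newick_type_labels(self):
        tree = chron.EventTree.from_newick(TWO_TIP)
        assert tree.root.name == "root" and tree.root.node_type == "wgd"
        assert tree["split"].node_type == "speciation"
        assert {t.name for t in tree.tips} == {"A", "B"}

    def test_legume_topology_has_eleven_branches(self):
        tree = chron.legume_demo_tree()
        assert len(tree.branch_nodes) == 11
        dups = [n for n in tree.preorder() if n.node_type in ("wgd", "wgt")]
        assert len(dups) == 3  # root WGD, Glycine WGD, genistoid WGT

    def test_duplication_nodes_unary(self):
        tree = chron.legume_demo_tree()
        for n in tree.preorder():
            if n.node_type in ("wgd", "wgt") and n is not tree.root:
                assert len(n.children) == 1

    def test_path_to_non_ancestor_errors(self):
        tree = chron.legume_demo_tree()
        with pytest.raises(chron.TopologyError):
            tree.path_up("Lupinus", "glycine_wgd")


class TestBuildSystem:
    def test_two_tip_design_matrix(self):
        tree = two_tip_tree()
        obs = [
            chron.ModalObservation("ortholog", "A", "B", 0.20),
            chron.ModalObservation("paralog", "A", "root", 0.24),
            chron.ModalObservation("paralog", "B", "root", 0.16),
        ]
        A, d, names = chron.build_system(tree, obs)
        assert names == ["A", "B"]
        assert A.tolist() == [[1, 1], [2, 0], [0, 2]]
        assert d.tolist() == [0.20, 0.24, 0.16]

    def test_duplicate_observations_duplicate_rows(self):
        tree = two_tip_tree()
        obs = [chron.ModalObservation("ortholog", "A", "B", 0.2)] * 2
        A, d, _ = chron.build_system(tree, obs)
        assert A.shape == (2, 2) and np.array_equal(A[0], A[1])

    def test_legume_system_has_eleven_columns(self):
        tree = chron.legume_demo_tree()
        obs = simulate.simulate_modal_distances(tree, 0.0, seed=1)
        A, _, _ = chron.build_system(tree, obs)
        assert A.shape[1] == 11

    def test_paralog_to_non_duplication_rejected(self):
        tree = chron.legume_demo_tree()
        obs = [chron.ModalObservation("paralog", "Lupinus", "radiation", 0.3)]
        with pytest.raises(chron.TopologyError):
            chron.build_system(tree, obs)


class TestSolve:
    def test_exact_two_by_two(self):
        tree = two_tip_tree()
        obs = [
            chron.ModalObservation("ortholog", "A", "B", 0.20),
            chron.ModalObservation("paralog", "A", "root", 0.24),
            chron.ModalObservation("paralog", "B", "root", 0.16),
        ]
        A, d, names = chron.build_system(tree, obs)
        res = chron.solve_branch_lengths(A, d, names)
        assert res.lengths["A"] == pytest.approx(0.12, abs=1e-12)
        assert res.lengths["B"] == pytest.approx(0.08, abs=1e-12)
        assert res.residual == pytest.approx(0, abs=1e-12)

    def test_underdetermined_detected(self):
        tree = two_tip_tree()
        obs = [chron.ModalObservation("ortholog", "A", "B", 0.2)]
        A, d, names = chron.build_system(tree, obs)
        with pytest.raises(chron.UnderDeterminedError):
            chron.solve_branch_lengths(A, d, names)

    def test_noiseless_roundtrip_on_random_trees(self, rng):
        for trial in range(10):
            tree = random_event_tree(rng, n_tips=5)
            truth = tree.lengths()
            obs = simulate.simulate_modal_distances(tree, 0.0, seed=trial)
            A, d, names = chron.build_system(tree, obs)
            res = chron.solve_branch_lengths(A, d, names)
            for name, value in truth.items():
                assert res.lengths[name] == pytest.approx(value, abs=1e-9)
            assert res.residual < 1e-9


class TestAssignDates:
    def test_two_tip_rates(self):
        tree = two_tip_tree()
        tree.set_lengths({"A": 0.12, "B": 0.08})
        result = chron.assign_dates(tree, 58.0)
        assert result.node_ages["root"] == 58.0
        assert result.node_ages["A"] == 0.0
        assert result.branch_rates["A"] == pytest.approx(0.12 / 58)
        assert result.branch_rates["B"] == pytest.approx(0.08 / 58)

    def test_wgt_age_from_two_peak_reduction(self):
        """Single lineage: WGT paralog peak 0.30, root paralog peak 0.74,
        calibration 58 Mya -> WGT age 58 * 0.15/0.37 ~ 23.5 Mya."""
        tree = chron.EventTree.from_newick("((Tip)wgt:type=wgt)root:type=wgd;")
        obs = [
            chron.ModalObservation("paralog", "Tip", "wgt", 0.30),
            chron.ModalObservation("paralog", "Tip", "root", 0.74),
        ]
        result = chron.solve_chronology(tree, obs, 58.0)
        assert result.node_ages["wgt"] == pytest.approx(58 * 0.15 / 0.37, abs=1e-9)
        assert result.node_ages["wgt"] == pytest.approx(23.5, abs=0.1)

    def test_equal_branches_clock_limit(self):
        tree = chron.EventTree.from_newick("((A,B)inner,C)root:type=wgd;")
        tree.set_lengths({n.name: 0.1 for n in tree.branch_nodes})
        ages = chron.assign_dates(tree, 60.0).node_ages
        assert ages["inner"] == pytest.approx(30.0)

    def test_age_monotonic_root_to_tip(self, rng):
        for trial in range(5):
            tree = random_event_tree(rng, n_tips=5)
            ages = chron.assign_dates(tree, 58.0).node_ages
            for node in tree.branch_nodes:
                assert ages[node.parent.name] >= ages[node.name] - 1e-9

    def test_zero_length_root_path_rejected(self):
        tree = two_tip_tree()
        tree.set_lengths({"A": 0.0, "B": 0.1})
        with pytest.raises(ValueError):
            chron.assign_dates(tree, 58.0)


def random_event_tree(rng, n_tips=5):
    """Random rooted binary topology with a WGD root and 1-2 extra
    duplication nodes inserted on random branches; random branch lengths."""
    names = [f"t{i}" for i in range(n_tips)]
    nodes = [chron.EventNode(n, "tip") for n in names]
    k = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = chron.EventNode(f"s{k}", "speciation", [left, right])
        left.parent = right.parent = parent
        k += 1
        nodes.append(parent)
    root = chron.EventNode("root", "wgd", [nodes[0]])
    nodes[0].parent = root
    tree = chron.EventTree(root)
    # insert duplication nodes on random tip branches
    for d in range(int(rng.integers(1, 3))):
        tip = tree.tips[int(rng.integers(n_tips))]
        dup = chron.EventNode(f"dup{d}_{tip.name}", "wgd", [tip], tip.parent)
        tip.parent.children[tip.parent.children.index(tip)] = dup
        tip.parent = dup
        tree = chron.EventTree(root)
    lengths = {
        n.name: float(rng.uniform(0.02, 0.4)) for n in tree.branch_nodes
    }
    tree.set_lengths(lengths)
    return tree


class TestNoiseRecovery:
    def test_median_age_error_under_noise(self):
        """Gaussian noise sd 0.01 on the legume topology: median internal
        node age error below 3 My over 50 replicates."""
        tree = chron.legume_demo_tree()
        truth_ages = chron.assign_dates(tree, 58.0).node_ages
        internal = [
            n.name for n in tree.preorder() if n.children and n is not tree.root
        ]
        errors = []
        for rep in range(50):
            obs = simulate.simulate_modal_distances(tree, 0.01, seed=1000 + rep)
            try:
                result = chron.solve_chronology(tree, obs, 58.0)
            finally:
                tree.set_lengths(chron.LEGUME_BRANCH_KS)
            errors.extend(
                abs(result.node_ages[n] - truth_ages[n]) for n in internal
            )
        assert np.median(errors) < 3.0

    def test_branch_length_rmse_small_noise(self):
        tree = chron.legume_demo_tree()
        truth = dict(chron.LEGUME_BRANCH_KS)
        sq = []
        for rep in range(50):
            obs = simulate.simulate_modal_distances(tree, 0.01, seed=2000 + rep)
            A, d, names = chron.build_system(tree, obs)
            res = chron.solve_branch_lengths(A, d, names)
            sq.extend((res.lengths[n] - truth[n]) ** 2 for n in names)
        assert np.sqrt(np.mean(sq)) < 0.02


class TestObservationIO:
    def test_round_trip(self, tmp_path):
        obs = [
            chron.ModalObservation("ortholog", "A", "B", 0.2),
            chron.ModalObservation("paralog", "A", "root", 0.24, through_root=False),
        ]
        path = tmp_path / "obs.tsv"
        chron.observations_to_frame(obs).to_csv(path, sep="\t", index=False)
        back = chron.read_observations(path)
        assert [(o.kind, o.node_a, o.node_b, o.modal_ks) for o in back] == [
            (o.kind, o.node_a, o.node_b, o.modal_ks) for o in obs
        ]
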