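import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, spearmanr

from spatglia import syndata, trajectory
from spatglia.preprocess import NormalizedMatrix, log_normalize
from spatglia.trajectory import (MICROGLIAL_PANEL, PrincipalGraph,
                                 compute_pseudotime,
                                 expression_along_pseudotime,
                                 extract_branches, learn_principal_graph,
                                 map_pseudotime_spatial, panel_embedding,
                                 rank_branches_by_gene, select_root)


def _path_graph(n_nodes=4):
    """Unit-spaced path graph with one spot projected at each node."""
    coords = np.column_stack([np.arange(n_nodes, dtype=float),
                              np.zeros(n_nodes)])
    edges = [(i, i + 1) for i in range(n_nodes - 1)]
    spot_edge = np.array([min(i, n_nodes - 2) for i in range(n_nodes)])
    spot_t = np.array([0.0 if i < n_nodes - 1 else 1.0
                       for i in range(n_nodes)])
    return PrincipalGraph(coords, edges, np.ones(n_nodes - 1), spot_edge,
                          spot_t, np.arange(n_nodes))


class TestPanelEmbedding:
    def test_small_panel_caps_component_count(self, small_study):
        with pytest.warns(UserWarning, match="PCs"):
            emb, used = panel_embedding(small_study.data,
                                        panel=["Lpl", "Cst7"], n_pcs=10)
        assert emb.scores.shape[1] == 2
        assert used == ["Lpl", "Cst7"]

    def test_missing_majority_of_panel_is_an_error(self, small_study):
        panel = ["Lpl", "NopeA", "NopeB", "NopeC"]
        with pytest.raises(ValueError, match="missing"):
            panel_embedding(small_study.data, panel=panel)

    def test_archetype_split_lands_on_pc1(self):
        # homeostatic-high vs DAM-high archetypes separate perfectly
        sd = syndata.gradient_dataset(n_spots=200, n_genes=120, seed=5)
        u = sd.activation["activated"].to_numpy()
        emb, _ = panel_embedding(sd.data)
        lo, hi = u < 0.2, u > 0.8
        s = emb.scores[:, 0]
        auc_split = (s[hi].min() > s[lo].max()) or (s[hi].max() < s[lo].min())
        assert abs(spearmanr(s, u).statistic) > 0.85
        assert auc_split or abs(s[hi].mean() - s[lo].mean()) > 2 * s.std()


class TestLearnGraph:
    def test_noiseless_segment_gives_path_graph(self):
        x = np.linspace(0, 10, 120)
        emb = np.column_stack([x, np.zeros(120)])
        g = learn_principal_graph(emb, n_nodes=6, seed=0)
        assert len(g.edges) == g.n_nodes - 1
        degrees = np.zeros(g.n_nodes, int)
        for u, v in g.edges:
            degrees[u] += 1
            degrees[v] += 1
        assert sorted(degrees)[:2] == [1, 1] and max(degrees) == 2
        pt = compute_pseudotime(g, int(np.argmin(g.node_coords[:, 0])))
        # projections are ordered by coordinate (weakly: spots beyond the
        # contracted tree ends tie at the boundary pseudotime)
        assert (np.diff(pt.pseudotime[np.argsort(x)]) >= -1e-9).all()
        assert spearmanr(pt.pseudotime, x).statistic > 0.98

    def test_y_shape_gives_three_leaves(self, rng):
        arms = [np.column_stack([np.linspace(0, 5, 60), np.zeros(60)]),
                np.column_stack([np.linspace(0, -4, 60),
                                 np.linspace(0, 4, 60)]),
                np.column_stack([np.linspace(0, -4, 60),
                                 np.linspace(0, -4, 60)])]
        emb = np.vstack(arms)
        g = learn_principal_graph(emb, n_nodes=9, seed=1)
        degrees = np.zeros(g.n_nodes, int)
        for u, v in g.edges:
            degrees[u] += 1
            degrees[v] += 1
        assert (degrees == 1).sum() == 3

    def test_tree_invariants_on_learned_graphs(self):
        sd = syndata.gradient_dataset(n_spots=400, seed=9)
        emb, _ = panel_embedding(sd.data)
        g = learn_principal_graph(emb, seed=2)
        assert len(g.edges) == g.n_nodes - 1
        import networkx as nx
        assert nx.is_connected(g.tree())
        assert len(g.spot_edge) == 400

    def test_degenerate_embedding_gives_single_node(self):
        with pytest.warns(UserWarning, match="degenerate"):
            g = learn_principal_graph(np.zeros((50, 3)), seed=0)
        assert g.n_nodes == 1 and len(g.edges) == 0

    def test_too_few_spots_rejected(self):
        with pytest.raises(ValueError, match="10 spots"):
            learn_principal_graph(np.zeros((5, 2)), seed=0)


class TestSelectRoot:
    def test_root_is_leaf_with_minimal_late_fraction(self):
        g = _path_graph(4)
        geno = np.array(["WT", "WT", "AD", "AD"])
        age = np.array(["3M", "7M", "7M", "7M"])
        root, enrich = select_root(g, geno, age)
        assert root == 0
        assert enrich.loc[enrich["node"] == 3, "late_fraction"].iloc[0] == 1.0

    def test_tie_broken_by_smallest_id_with_warning(self):
        g = _path_graph(3)
        geno = np.array(["WT", "AD", "WT"])
        age = np.array(["3M", "7M", "3M"])
        with pytest.warns(UserWarning, match="tie"):
            root, _ = select_root(g, geno, age)
        assert root == 0

    def test_root_lands_on_wt_pole_of_gradient(self):
        hits = 0
        for r in range(5):
            sd = syndata.gradient_dataset(seed=700 + r)
            emb, _ = panel_embedding(sd.data)
            g = learn_principal_graph(emb, seed=r)
            root, _ = select_root(g, sd.data.meta["genotype"].to_numpy(),
                                  sd.data.meta["age"].to_numpy())
            u = sd.activation["activated"].to_numpy()
            hits += u[g.spot_node == root].mean() < np.median(u)
        assert hits == 5


class TestPseudotime:
    def test_unit_path_gives_integer_node_times(self):
        g = _path_graph(4)
        pt = compute_pseudotime(g, 0)
        assert np.allclose(pt.node_pseudotime, [0, 1, 2, 3])
        assert np.allclose(pt.pseudotime, [0, 1, 2, 3])

    def test_rerooting_reverses_order(self):
        g = _path_graph(5)
        a = compute_pseudotime(g, 0).pseudotime
        b = compute_pseudotime(g, 4).pseudotime
        assert spearmanr(a, b).statistic == pytest.approx(-1.0)

    def test_pseudotime_is_lipschitz_along_tree(self):
        sd = syndata.gradient_dataset(n_spots=300, seed=13)
        emb, _ = panel_embedding(sd.data)
        g = learn_principal_graph(emb, seed=3)
        pt = compute_pseudotime(g, g.leaves()[0])
        import networkx as nx
        dist = dict(nx.all_pairs_dijkstra_path_length(g.tree()))
        for a in range(g.n_nodes):
            for b in range(g.n_nodes):
                assert (abs(pt.node_pseudotime[a] - pt.node_pseudotime[b])
                        <= dist[a][b] + 1e-9)

    def test_gradient_recovery(self):
        sd = syndata.gradient_dataset(seed=778)
        emb, _ = panel_embedding(sd.data)
        g = learn_principal_graph(emb, seed=0)
        root, _ = select_root(g, sd.data.meta["genotype"].to_numpy(),
                              sd.data.meta["age"].to_numpy())
        pt = compute_pseudotime(g, root)
        u = sd.activation["activated"].to_numpy()
        assert abs(spearmanr(pt.pseudotime, u).statistic) >= 0.9
        # orientation: late-group membership correlates positively
        late = ((sd.data.meta["genotype"] == "AD")
                & (sd.data.meta["age"] == "7M")).to_numpy()
        assert np.corrcoef(late.astype(float), pt.pseudotime)[0, 1] > 0

    def test_invalid_root_rejected(self):
        with pytest.raises(ValueError, match="root"):
            compute_pseudotime(_path_graph(3), 7)


class TestBranches:
    def test_path_graph_has_one_branch(self):
        branches = extract_branches(_path_graph(4), 0)
        assert len(branches) == 1
        assert branches[0].node_path == [0, 1, 2, 3]
        assert not branches[0].shared.any()

    def test_y_graph_rooted_at_leaf_has_two_branches_with_shared_trunk(self):
        # star: center 0, leaves 1..3; root at leaf 1
        coords = np.array([[0, 0], [1, 0], [-1, 1], [-1, -1]], dtype=float)
        edges = [(0, 1), (0, 2), (0, 3)]
        spot_edge = np.array([0, 0, 1, 2])
        spot_t = np.array([0.5, 0.9, 0.5, 0.5])
        g = PrincipalGraph(coords, edges, np.ones(3), spot_edge, spot_t,
                           np.array([0, 1, 2, 3]))
        branches = extract_branches(g, 1)
        assert len(branches) == 2
        # spots on the trunk edge (0,1) belong to both branches, flagged
        for b in branches:
            assert b.spot_mask[0] and b.spot_mask[1]
            assert b.shared[0] and b.shared[1]

    def test_single_node_graph_has_no_branches(self):
        with pytest.warns(UserWarning):
            g = learn_principal_graph(np.zeros((50, 2)), seed=0)
        with pytest.warns(UserWarning, match="no branches"):
            assert extract_branches(g, 0) == []


class TestSpatialMapping:
    def test_branch_records_match_membership_bit_exactly(self):
        g = _path_graph(4)
        pt = compute_pseudotime(g, 0)
        branch = extract_branches(g, 0)[0]
        pos = pd.DataFrame({"x_px": [0., 1, 2, 3], "y_px": [0., 0, 0, 0]},
                           index=[f"s{i}" for i in range(4)])
        out = map_pseudotime_spatial(pt, pos, branch)
        assert len(out) == int(branch.spot_mask.sum())
        assert np.array_equal(out["pseudotime"].to_numpy(),
                              pt.pseudotime[branch.spot_mask])

    def test_misaligned_positions_rejected(self):
        g = _path_graph(4)
        pt = compute_pseudotime(g, 0)
        branch = extract_branches(g, 0)[0]
        pos = pd.DataFrame({"x_px": [0.0], "y_px": [0.0]})
        with pytest.raises(ValueError, match="aligned"):
            map_pseudotime_spatial(pt, pos, branch)

    def test_wm_spots_lead_gm_spots_at_3_months(self):
        # AD-3M activation is WM-high / GM-low, so on a WT+AD-3M study the
        # WM spots must sit later along the activation trajectory
        study = syndata.simulate_study(
            seed=55, n_rows=20, n_cols=25, n_genes=500, n_region_markers=25,
            dam_fold=4.0,
            samples=[("WT", "3M", "rep1"), ("AD", "3M", "rep1")])
        emb, _ = panel_embedding(study.data)
        g = learn_principal_graph(emb, seed=0)
        root, _ = select_root(g, study.data.meta["genotype"].to_numpy(),
                              study.data.meta["age"].to_numpy(),
                              late_group=("AD", "3M"))
        pt = compute_pseudotime(g, root)
        meta = study.data.meta
        ad = (meta["genotype"] == "AD").to_numpy()
        wm = (meta["region"] == "WM").to_numpy()
        gm = meta["region"].isin(syndata.GM_REGIONS).to_numpy()
        assert (pt.pseudotime[ad & wm].mean()
                > pt.pseudotime[ad & gm].mean())


class TestExpressionCurves:
    def _assignment(self, n=100, seed=0):
        sd = syndata.gradient_dataset(n_spots=300, seed=seed)
        emb, _ = panel_embedding(sd.data)
        g = learn_principal_graph(emb, seed=0)
        root, _ = select_root(g, sd.data.meta["genotype"].to_numpy(),
                              sd.data.meta["age"].to_numpy())
        return sd, compute_pseudotime(g, root)

    def test_constant_gene_gives_flat_curve(self, rng):
        sd, pt = self._assignment(seed=17)
        X = np.full((1, 300), 2.5)
        norm = NormalizedMatrix(
            __import__("scipy.sparse", fromlist=["csr_matrix"]).csr_matrix(X),
            np.array(["flat"], dtype=object), sd.data.spot_ids)
        curve = expression_along_pseudotime(norm, pt, ["flat"], n_windows=10)
        assert curve["mean"].nunique() == 1

    def test_activated_gene_rises_monotonically(self):
        sd, pt = self._assignment(seed=18)
        norm = log_normalize(sd.data)
        curve = expression_along_pseudotime(norm, pt, ["Trem2"],
                                            n_windows=10)
        tau = kendalltau(curve["window"], curve["mean"]).statistic
        assert tau >= 0.8

    def test_single_window_is_global_mean(self):
        sd, pt = self._assignment(seed=19)
        norm = log_normalize(sd.data)
        curve = expression_along_pseudotime(norm, pt, ["Trem2"], n_windows=1)
        assert len(curve) == 1
        assert curve["mean"].iloc[0] == pytest.approx(
            norm.gene_values("Trem2").mean())

    def test_empty_selection_rejected(self):
        sd, pt = self._assignment(seed=20)
        norm = log_normalize(sd.data)
        with pytest.raises(ValueError, match="empty"):
            expression_along_pseudotime(norm, pt, ["Trem2"],
                                        spot_mask=np.zeros(300, bool))

    def test_branches_ranked_by_marker_expression(self):
        sd, pt = self._assignment(seed=21)
        branches = extract_branches(pt.graph, pt.root)
        norm = log_normalize(sd.data)
        table = rank_branches_by_gene(norm, branches, "Axl")
        assert list(table.columns) == ["branch_id", "leaf", "mean_expression"]
        assert table["mean_expression"].is_monotonic_decreasing


def test_panel_has_28_unique_genes():
    assert len(MICROGLIAL_PANEL) == 28
    assert len(set(MICROGLIAL_PANEL)) == 28
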