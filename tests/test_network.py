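import networkx as nx
import numpy as np
import pytest

from melnet.coexpression import spearman_matrix
from melnet.dataio import DataFormatError, PerturbationDesign
from melnet.network import (
    ConsensusNetwork,
    SubnetworkDAG,
    consensus_network,
    find_hubs,
    fit_subnetwork,
    hub_conservation,
    parent_knockdown_consistency,
    sample_neighbourhoods,
)
from melnet.preprocess import batch_median_scale
from melnet.synthetic import (
    GeneratorConfig,
    generate_truth,
    simulate_perturbation_dataset,
    stage_seed,
)

from conftest import make_expr


@pytest.fixture(scope="module")
def net_data(small_net_cfg):
    truth = generate_truth(small_net_cfg)
    expr, design = simulate_perturbation_dataset(truth, small_net_cfg)
    scaled = batch_median_scale(expr)
    corr = spearman_matrix(scaled)
    return truth, expr, design, scaled, corr


@pytest.fixture(scope="module")
def subnets(net_data, small_net_cfg):
    _truth, _expr, _design, scaled, corr = net_data
    neigh = sample_neighbourhoods(
        corr, 200, 15, seed=stage_seed(small_net_cfg.seed, "network")
    )
    return [fit_subnetwork(scaled, nodes) for nodes in neigh]


class TestSampleNeighbourhoods:
    def test_cycling_seeds_cover_every_gene(self, net_data):
        corr = net_data[4]
        n = len(corr.gene_ids)
        sets = sample_neighbourhoods(corr, n, 5, seed=0)
        covered = set().union(*map(set, sets))
        assert covered == set(corr.gene_ids)

    def test_deterministic_given_seed(self, net_data):
        corr = net_data[4]
        assert sample_neighbourhoods(corr, 30, 8, seed=3) == sample_neighbourhoods(
            corr, 30, 8, seed=3
        )

    def test_neighbourhood_contains_module_mates_on_clean_data(self):
        cfg = GeneratorConfig(
            n_genes=30, n_modules=3, module_size_range=(6, 8),
            noise_sd=0.01, batch_shift_sd=0.0, n_batches=1, seed=2,
        )
        truth = generate_truth(cfg)
        expr, _ = simulate_perturbation_dataset(truth, cfg)
        corr = spearman_matrix(expr)
        sets = sample_neighbourhoods(corr, len(corr.gene_ids), 8, seed=0)
        active = set(truth.active_modules("perturbation"))
        # on near-noiseless data every active-module gene has at least one
        # neighbourhood dominated by its module mates
        for m in active:
            module = set(truth.genes_in_module(m))
            for g in module:
                best = max(
                    len(set(nodes) & module) for nodes in sets if g in nodes
                )
                assert best >= min(len(module), 8) - 1

    def test_size_bounds_enforced(self, net_data):
        corr = net_data[4]
        with pytest.raises(DataFormatError):
            sample_neighbourhoods(corr, 5, 2, seed=0)
        with pytest.raises(DataFormatError):
            sample_neighbourhoods(corr, 5, 9999, seed=0)


class TestFitSubnetwork:
    def test_strong_dependence_yields_single_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = x + 0.05 * rng.normal(size=50)
        expr = make_expr([x, y])
        dag = fit_subnetwork(expr, ["g0", "g1"])
        assert len(dag.edges) == 1

    def test_independent_noise_gives_empty_graph(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(size=(6, 40)))
        dag = fit_subnetwork(expr, expr.gene_ids)
        assert dag.edges == frozenset()

    def test_every_fitted_subnetwork_is_acyclic(self, subnets):
        for sn in subnets:
            g = nx.DiGraph(list(sn.edges))
            assert nx.is_directed_acyclic_graph(g)  # topological sort exists

    def test_max_parents_respected(self, subnets):
        for sn in subnets:
            parents = {}
            for p, c in sn.edges:
                parents.setdefault(c, set()).add(p)
            assert all(len(ps) <= 3 for ps in parents.values())

    def test_sample_floor_enforced(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(DataFormatError):
            fit_subnetwork(expr, expr.gene_ids)

    def test_cycle_in_constructed_dag_rejected(self):
        with pytest.raises(DataFormatError):
            SubnetworkDAG(("a", "b"), frozenset({("a", "b"), ("b", "a")}), 0.0)


class TestConsensus:
    def _toy_subnets(self):
        # edge (a,b) present in 2 of the 5 subnets containing both endpoints;
        # (c,d) present in 1 of 10
        subnets = []
        for i in range(5):
            edges = {("a", "b")} if i < 2 else set()
            subnets.append(SubnetworkDAG(("a", "b"), frozenset(edges), 0.0))
        for i in range(10):
            edges = {("c", "d")} if i == 0 else set()
            subnets.append(SubnetworkDAG(("c", "d"), frozenset(edges), 0.0))
        return subnets

    def test_cooccurrence_frequencies_and_threshold(self):
        net = consensus_network(self._toy_subnets(), 0.2, denominator="cooccurrence")
        assert net.edges == {("a", "b"): pytest.approx(0.4)}  # 2/5 kept, 1/10 dropped

    def test_all_subnetworks_denominator(self):
        net = consensus_network(self._toy_subnets(), 0.1, denominator="all")
        assert net.edges == {("a", "b"): pytest.approx(2 / 15)}

    def test_edge_set_antitone_in_threshold(self, subnets):
        sizes = [
            len(consensus_network(subnets, t).edges)
            for t in np.arange(0.1, 0.95, 0.05)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_undirected_mode_pools_directions(self, subnets):
        directed = consensus_network(subnets, 0.2, directed=True)
        undirected = consensus_network(subnets, 0.2, directed=False)
        assert all(a <= b for a, b in undirected.edges)
        # pooling can only merge evidence: at least as many undirected pairs
        directed_pairs = {tuple(sorted(e)) for e in directed.edges}
        assert directed_pairs <= set(undirected.edges)

    def test_threshold_bounds(self, subnets):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(DataFormatError):
                consensus_network(subnets, bad)

    def test_deterministic_rebuild(self, net_data, small_net_cfg):
        _t, _e, _d, scaled, corr = net_data
        seed = stage_seed(small_net_cfg.seed, "network")
        neigh = sample_neighbourhoods(corr, 100, 12, seed=seed)
        n1 = consensus_network([fit_subnetwork(scaled, n) for n in neigh], 0.2)
        n2 = consensus_network([fit_subnetwork(scaled, n) for n in neigh], 0.2)
        assert n1.edges == n2.edges


class TestHubs:
    def _star(self, n_children=7):
        edges = {(f"hub", f"c{i}"): 0.5 for i in range(n_children)}
        return ConsensusNetwork(edges, 0.2)

    def test_star_centre_found(self):
        hubs = find_hubs(self._star(), min_children=5)
        assert len(hubs) == 1
        assert hubs[0].gene == "hub" and hubs[0].n_children == 7

    def test_threshold_above_max_degree_empty(self):
        assert find_hubs(self._star(), min_children=8) == []

    def test_sorted_by_degree_then_gene(self):
        edges = {("b", f"x{i}"): 0.5 for i in range(3)}
        edges.update({("a", f"y{i}"): 0.5 for i in range(3)})
        edges.update({("z", f"w{i}"): 0.5 for i in range(5)})
        hubs = find_hubs(ConsensusNetwork(edges, 0.2), 1)
        assert [h.gene for h in hubs] == ["z", "a", "b"]

    def test_true_hubs_recovered_from_consensus(self, net_data, subnets):
        truth = net_data[0]
        net = consensus_network(subnets, 0.2)
        hubs = find_hubs(net, min_children=5)
        found = {h.gene for h in hubs}
        active_hubs = {
            truth.hub_of_module[m] for m in truth.active_modules("perturbation")
        }
        assert len(active_hubs & found) / len(active_hubs) >= 0.7


class TestHubConservation:
    def test_self_dataset_counts_are_maximal(self, net_data, subnets):
        _t, _e, _d, scaled, _c = net_data
        net = consensus_network(subnets, 0.2)
        hubs = find_hubs(net, 5)
        annotated = hub_conservation(
            net, scaled, rho_threshold=0.4, min_conserved_children=5, hubs=hubs
        )
        for h in annotated:
            assert h.measurable
            assert h.n_conserved_children == h.n_children  # training data itself

    def test_shared_hub_conserved_perturbation_only_not(
        self, net_data, subnets, small_net_cfg
    ):
        from melnet.synthetic import simulate_tumour_cohort

        truth = net_data[0]
        tum = simulate_tumour_cohort(truth, small_net_cfg)
        net = consensus_network(subnets, 0.2)
        hubs = find_hubs(net, 5)
        annotated = {h.gene: h for h in hub_conservation(
            net, tum, rho_threshold=0.4, min_conserved_children=5, hubs=hubs
        )}
        for m in truth.active_modules("perturbation"):
            hub = truth.hub_of_module[m]
            if hub not in annotated:
                continue
            if truth.module_kind[m] == "shared":
                assert annotated[hub].conserved
            elif truth.module_kind[m] == "perturbation_only":
                assert not annotated[hub].conserved

    def test_exact_copy_required_at_threshold_one(self, net_data, subnets):
        _t, _e, _d, scaled, _c = net_data
        rng = np.random.default_rng(0)
        noisy = scaled.values + rng.normal(0, 0.05, scaled.values.shape)
        other = make_expr(
            noisy.to_numpy(), genes=scaled.gene_ids, samples=scaled.sample_ids
        )
        net = consensus_network(subnets, 0.2)
        hubs = find_hubs(net, 5)
        annotated = hub_conservation(
            net, other, rho_threshold=1.0, min_conserved_children=1, hubs=hubs
        )
        assert all(h.n_conserved_children == 0 for h in annotated)

    def test_missing_hub_flagged_unmeasurable(self, net_data, subnets):
        _t, _e, _d, scaled, _c = net_data
        net = consensus_network(subnets, 0.2)
        hubs = find_hubs(net, 5)
        reduced = scaled.subset_genes(
            [g for g in scaled.gene_ids if g != hubs[0].gene]
        )
        annotated = hub_conservation(net, reduced, hubs=hubs)
        assert not annotated[0].measurable
        assert annotated[0].conserved is False


class TestKnockdownConsistency:
    def test_sign_convention(self):
        # child at 2x / 0.5x its median in the knockdown sample -> +2 / -2
        # log2 values: parent's kd sample is s0
        child_up = [1.0, 0.0, 0.0, 0.0, 0.0]  # 2^1 vs median 2^0 -> ratio 2
        child_dn = [-1.0, 0.0, 0.0, 0.0, 0.0]
        parent = [0.4, 1.0, -0.2, 0.8, -1.1]
        expr = make_expr(
            [parent, child_up, child_dn], genes=["p", "up", "dn"],
        )
        design = PerturbationDesign(
            {"s0": "p", "s1": "CONTROL", "s2": "CONTROL", "s3": "CONTROL",
             "s4": "CONTROL"}
        )
        net = ConsensusNetwork({("p", "up"): 1.0, ("p", "dn"): 1.0}, 0.2)
        table = parent_knockdown_consistency(net, expr, design)
        ratios = dict(zip(table["child"], table["signed_ratio"]))
        assert ratios["up"] == pytest.approx(2.0)
        assert ratios["dn"] == pytest.approx(-2.0)

    def test_ratios_always_outside_open_unit_interval(
        self, net_data, subnets
    ):
        _t, expr, design, _s, _c = net_data
        net = consensus_network(subnets, 0.2)
        table = parent_knockdown_consistency(net, expr, design)
        assert len(table) > 0
        assert (table["signed_ratio"].abs() >= 1.0).all()

    def test_positive_rho_children_trend_down_after_parent_knockdown(
        self, net_data, subnets
    ):
        from scipy.stats import wilcoxon

        _t, expr, design, _s, _c = net_data
        net = consensus_network(subnets, 0.2)
        table = parent_knockdown_consistency(net, expr, design)
        pos = table[table["rho"] > 0.3]
        dev = np.where(
            pos["signed_ratio"] >= 1, pos["signed_ratio"] - 1,
            pos["signed_ratio"] + 1,
        )
        assert wilcoxon(dev, alternative="less").pvalue < 0.05

    def test_untargeted_parents_rejected(self, net_data):
        _t, expr, _d, _s, _c = net_data
        design = PerturbationDesign(
            {s: "CONTROL" for s in expr.sample_ids}
        )
        net = ConsensusNetwork({(expr.gene_ids[0], expr.gene_ids[1]): 1.0}, 0.2)
        with pytest.raises(DataFormatError):
            parent_knockdown_consistency(net, expr, design)
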