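import numpy as np
import pandas as pd
import pytest

from conftest import ring_of_cliques, two_cliques
from empanet.community import (
    DEFAULT_GAMMA_GRID,
    AgreementMatrix,
    Partition,
    agreement,
    consensus_partition,
    gamma_sweep,
    louvain_finetune,
    modularity_q,
    module_significance,
    modularity_trait_correlation,
)
from oracles import random_graph


class TestModularity:
    def test_single_module_is_zero_at_unit_gamma(self, rng):
        adj = random_graph(10, 0.4, rng)
        assert modularity_q(adj, np.zeros(10, dtype=int), 1.0) == pytest.approx(0.0)

    def test_two_cliques_bipartition_is_half(self):
        adj = two_cliques(5)
        labels = np.array([0] * 5 + [1] * 5)
        assert modularity_q(adj, labels, 1.0) == pytest.approx(0.5)

    def test_singleton_partition_matches_formula(self, rng):
        adj = random_graph(8, 0.5, rng)
        k = adj.sum(axis=1)
        two_m = adj.sum()
        gamma = 1.7
        expected = (0 - gamma * np.sum(k**2) / two_m**2)
        got = modularity_q(adj, np.arange(8), gamma)
        assert got == pytest.approx(expected)
        assert got <= 0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            modularity_q(np.zeros((4, 4)), np.zeros(4, dtype=int), 1.0)


class TestLouvainFinetune:
    def test_two_cliques_exact_optimum(self):
        part = louvain_finetune(two_cliques(5), gamma=1.0, seed=0)
        assert part.q == pytest.approx(0.5)
        assert part.n_modules == 2
        assert len(set(part.labels[:5])) == 1 and len(set(part.labels[5:])) == 1

    def test_ring_of_eight_cliques_recovered(self):
        adj = ring_of_cliques(8, 5)
        part = louvain_finetune(adj, gamma=1.0, seed=1)
        assert part.n_modules == 8
        expected = np.repeat(np.arange(8), 5)
        # same partition up to label names
        for m in range(8):
            assert len(set(part.labels[expected == m])) == 1

    def test_no_single_node_move_improves_q(self, rng):
        adj = random_graph(25, 0.25, rng)
        gamma = 1.0
        part = louvain_finetune(adj, gamma=gamma, seed=3)
        q0 = part.q
        for v in range(25):
            for target in range(part.n_modules + 1):  # +1: a fresh module
                labels = part.labels.copy()
                if labels[v] == target:
                    continue
                labels[v] = target
                assert modularity_q(adj, labels, gamma) <= q0 + 1e-10

    def test_beats_trivial_partitions(self, rng):
        adj = random_graph(20, 0.3, rng)
        for gamma in (0.5, 1.0, 2.0):
            part = louvain_finetune(adj, gamma=gamma, seed=5)
            assert part.q >= modularity_q(adj, np.zeros(20, dtype=int), gamma) - 1e-12
            assert part.q >= modularity_q(adj, np.arange(20), gamma) - 1e-12

    def test_deterministic_given_seed(self, rng):
        adj = random_graph(30, 0.2, rng)
        a = louvain_finetune(adj, gamma=1.3, seed=42)
        b = louvain_finetune(adj, gamma=1.3, seed=42)
        assert np.array_equal(a.labels, b.labels) and a.q == b.q

    def test_high_gamma_gives_no_fewer_modules(self, rng):
        adj = random_graph(30, 0.25, rng)
        low = louvain_finetune(adj, gamma=0.3, seed=7)
        high = louvain_finetune(adj, gamma=5.0, seed=7)
        assert high.n_modules >= low.n_modules


class TestGammaSweep:
    def test_default_grid_has_48_resolutions(self, rng):
        assert len(DEFAULT_GAMMA_GRID) == 48
        assert DEFAULT_GAMMA_GRID[0] == 0.3 and DEFAULT_GAMMA_GRID[-1] == 5.0

    def test_single_gamma_equals_finetune(self, rng):
        adj = random_graph(20, 0.3, rng)
        sweep = gamma_sweep(adj, gammas=(1.0,), seed=9)
        assert len(sweep) == 1
        assert sweep[0].q == pytest.approx(
            louvain_finetune(adj, 1.0, seed=np.random.default_rng(
                np.random.SeedSequence(9).spawn(1)[0])).q
        )

    def test_rejects_non_increasing_grid(self, rng):
        with pytest.raises(ValueError, match="increasing"):
            gamma_sweep(random_graph(10, 0.5, rng), gammas=(1.0, 0.5), seed=0)

    def test_q_decreases_and_modules_increase_with_gamma(self, rng):
        adj = ring_of_cliques(6, 5)
        sweep = gamma_sweep(adj, gammas=(0.3, 1.0, 2.0, 4.0), seed=11)
        qs = [p.q for p in sweep]
        mods = [p.n_modules for p in sweep]
        assert np.all(np.diff(qs) <= 1e-12)
        assert np.all(np.diff(mods) >= 0)


class TestAgreement:
    def test_identical_partitions(self):
        labels = np.array([0, 0, 1, 1, 2])
        agr = agreement([labels] * 10)
        assert set(np.unique(agr.counts)) <= {0, 10}
        assert agr.counts[0, 1] == 10 and agr.counts[0, 2] == 0

    def test_pair_together_once(self):
        a = np.array([0, 0, 1])
        b = np.array([0, 1, 1])
        agr = agreement([a, b])
        assert agr.counts[0, 1] == 1

    def test_matches_brute_force_tally(self, rng):
        parts = [rng.integers(0, 4, size=12) for _ in range(6)]
        agr = agreement(parts)
        for i in range(12):
            for j in range(12):
                expected = sum(1 for p in parts if p[i] == p[j])
                assert agr.counts[i, j] == expected

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="same node set"):
            agreement([np.zeros(3, dtype=int), np.zeros(4, dtype=int)])


class TestConsensus:
    def test_idempotent_on_identical_partitions(self):
        labels = np.array([0] * 5 + [1] * 5)
        agr = agreement([labels] * 12)
        cons = consensus_partition(agr, reps=20, seed=0)
        assert np.array_equal(cons.labels, np.array([0] * 5 + [1] * 5))

    def test_conflicting_partitions_deterministic(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        agr = agreement([a, b] * 5)
        c1 = consensus_partition(agr, reps=10, seed=3)
        c2 = consensus_partition(agr, reps=10, seed=3)
        assert np.array_equal(c1.labels, c2.labels)

    def test_planted_partition_recovery(self):
        from empanet.validation import consensus_recovery_ari

        ari = consensus_recovery_ari(
            n_subjects=25, n_nodes=60, n_modules=4, p_in=0.4, p_out=0.05,
            reps=25, seed=17,
        )
        assert ari >= 0.9


class TestModuleSignificance:
    def test_reproducible_modules_all_kept(self):
        labels = np.array([0] * 6 + [1] * 6)
        parts = [labels] * 15
        cons = Partition(gamma=1.0, labels=labels, q=0.5)
        keep = module_significance(cons, parts, n_null=50, seed=0)
        assert keep["keep"].all()

    def test_random_partitions_rarely_kept(self, rng):
        kept = total = 0
        for s in range(25):
            local = np.random.default_rng(s)
            parts = [local.integers(0, 4, 24) for _ in range(12)]
            cons = Partition(gamma=1.0, labels=local.integers(0, 4, 24), q=0.0)
            keep = module_significance(cons, parts, n_null=60, seed=s)
            informative = keep["size"] >= 2
            kept += int((keep["keep"] & informative).sum())
            total += int(informative.sum())
        assert kept / total < 0.15  # ~5% nominal under the null

    def test_single_module_kept_vacuously_with_warning(self):
        labels = np.zeros(6, dtype=int)
        cons = Partition(gamma=1.0, labels=labels, q=0.0)
        with pytest.warns(RuntimeWarning, match="single-module"):
            keep = module_significance(cons, [labels] * 5, n_null=10, seed=0)
        assert keep["keep"].all()


class TestModularityTraitCorrelation:
    @staticmethod
    def q_table(rng, n=100, gammas=(0.5, 1.0, 1.5), shift=None):
        rows = []
        for s in range(n):
            for g in gammas:
                q = rng.normal(0.5 - 0.1 * g, 0.05)
                if shift is not None:
                    q += shift[s]
                rows.append({"subject_id": f"S{s}", "gamma": g, "q": q})
        return pd.DataFrame(rows)

    def test_null_trait_uncorrelated(self, rng):
        qt = self.q_table(rng)
        traits = pd.Series(rng.standard_normal(100),
                           index=[f"S{s}" for s in range(100)])
        _, mean_r, _ = modularity_trait_correlation(qt, traits)
        assert abs(mean_r) < 0.1

    def test_trait_equal_to_q_perfectly_correlated(self, rng):
        shift = rng.standard_normal(100) * 0.2
        qt = self.q_table(rng, shift=shift)
        traits = pd.Series(shift + rng.normal(0, 1e-4, 100),
                           index=[f"S{s}" for s in range(100)])
        per_gamma, mean_r, _ = modularity_trait_correlation(qt, traits)
        assert (per_gamma["r"] > 0.9).all()

    def test_planted_correlation_recovered(self, rng):
        # subject-level Q shift correlated ~0.3 with the trait
        n = 400
        shift = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        sd_q = 0.05
        traits = pd.Series(shift * 0.3 + noise * np.sqrt(1 - 0.3**2),
                           index=[f"S{s}" for s in range(n)])
        qt = self.q_table(rng, n=n, shift=shift * sd_q)
        # planted r = 0.3 * corr(shift, Q) with Q noise sd 0.05 at each gamma
        _, mean_r, _ = modularity_trait_correlation(qt, traits)
        planted = 0.3 * sd_q / np.sqrt(sd_q**2 + 0.05**2)
        assert mean_r == pytest.approx(planted, abs=0.1)

    def test_zero_variance_gamma_excluded(self, rng):
        qt = pd.DataFrame(
            {"subject_id": ["A", "B", "C"] * 2, "gamma": [1.0] * 3 + [2.0] * 3,
             "q": [0.5, 0.5, 0.5, 0.4, 0.5, 0.6]}
        )
        traits = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "C"])
        with pytest.warns(RuntimeWarning, match="zero variance"):
            per_gamma, _, _ = modularity_trait_correlation(qt, traits)
        assert per_gamma["gamma"].tolist() == [2.0]


def test_agreement_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        AgreementMatrix(np.array([[2, 1], [0, 2]]), n_partitions=2)
    with pytest.raises(ValueError, match="\\[0, n_partitions\\]"):
        AgreementMatrix(np.full((2, 2), 5), n_partitions=2)


def test_adjusted_modularity_separates_structure_from_degree_null(rng):
    from conftest import ring_of_cliques
    from empanet.community import adjusted_modularity, louvain_finetune
    from oracles import random_graph

    ring = ring_of_cliques(6, 5)
    part = louvain_finetune(ring, gamma=1.0, seed=0)
    z_struct = adjusted_modularity(ring, part.labels, n_null=10, seed=1)
    er = random_graph(30, 0.3, rng)
    er_part = louvain_finetune(er, gamma=1.0, seed=0)
    z_er = adjusted_modularity(er, er_part.labels, n_null=10, seed=1)
    assert z_struct > 3.0       # strong planted structure
    assert abs(z_er) < 3.0      # random graph near its own null
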