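"""Distances, classical MDS, pairwise F_ST, AMOVA and the hybrid index."""

import numpy as np
import pandas as pd
import pytest

from aflpzone import dominant_freq as dfm
from aflpzone.aflp_io import AFLPDataset, PopulationHierarchy
from aflpzone.structure_stats import (
    DistanceMatrix,
    amova,
    classical_mds,
    classify_hybrids,
    hybrid_index,
    pairwise_distance,
    pairwise_fst,
)
from aflpzone.synthetic_data import (
    SimConfig,
    simulate_nested_design,
    simulate_parental_populations,
    simulate_race_structure,
    simulate_study,
)
from conftest import two_pop_hierarchy


def dataset_from_rows(rows):
    rows = np.asarray(rows, dtype=np.int8)
    return AFLPDataset(
        [f"i{k}" for k in range(rows.shape[0])],
        [f"L{k}" for k in range(rows.shape[1])],
        rows,
    )


class TestPairwiseDistance:
    def test_identical_vectors_distance_zero(self):
        ds = dataset_from_rows([[1, 0, 1], [1, 0, 1]])
        for kind in ("squared_euclidean", "one_minus_relatedness", "asymmetric_binary"):
            assert pairwise_distance(ds, kind).matrix[0, 1] == pytest.approx(0.0)

    def test_squared_euclidean_value(self):
        ds = dataset_from_rows([[1, 1, 0, 0], [0, 0, 1, 1]])
        assert pairwise_distance(ds, "squared_euclidean").matrix[0, 1] == pytest.approx(4.0)

    def test_asymmetric_binary_ignores_shared_absences(self):
        with_zeros = dataset_from_rows([[1, 0, 0, 0], [1, 0, 0, 0]])
        assert pairwise_distance(with_zeros, "asymmetric_binary").matrix[0, 1] == 0.0
        mixed = dataset_from_rows([[1, 0, 0, 0], [0, 1, 0, 0]])
        # one shared-absence pair of loci dropped: (b + c)/(a + b + c) = 2/2
        assert pairwise_distance(mixed, "asymmetric_binary").matrix[0, 1] == pytest.approx(1.0)

    def test_missing_cells_pairwise_deleted_and_rescaled(self):
        ds = dataset_from_rows([[1, 0, -1, 0], [0, 0, 1, 0]])
        # only 3 shared loci, 1 mismatch -> rescaled to 4/3
        assert pairwise_distance(ds, "squared_euclidean").matrix[0, 1] == pytest.approx(4 / 3)

    def test_no_shared_loci_is_error(self):
        ds = dataset_from_rows([[1, -1], [-1, 0]])
        with pytest.raises(ValueError, match="shares no"):
            pairwise_distance(ds)


class TestClassicalMDS:
    def test_equilateral_triangle_recovered(self):
        d2 = np.full((3, 3), 1.0)
        np.fill_diagonal(d2, 0.0)
        dm = DistanceMatrix(["a", "b", "c"], d2, "squared_euclidean")
        coords, _ = classical_mds(dm, 2)
        dists = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        off = dists[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0])

    def test_collinear_points_have_flat_second_axis(self, rng):
        x = np.sort(rng.uniform(0, 10, size=12))
        d2 = (x[:, None] - x[None, :]) ** 2
        dm = DistanceMatrix([f"i{k}" for k in range(12)], d2, "squared_euclidean")
        coords, evals = classical_mds(dm, 1)
        assert np.var(coords[:, 0]) > 0
        assert evals[1] == pytest.approx(0.0, abs=1e-8 * evals[0])

    def test_invalid_dims(self):
        d2 = np.array([[0.0, 1.0], [1.0, 0.0]])
        dm = DistanceMatrix(["a", "b"], d2, "squared_euclidean")
        with pytest.raises(ValueError):
            classical_mds(dm, 0)
        with pytest.raises(ValueError, match="positive eigenvalues"):
            classical_mds(dm, 2)

    def test_race_structure_separates_races(self):
        """The simulated 3-race island design yields race-coherent clusters
        in two MDS dimensions (positive silhouette against race labels)."""
        ds, hier = simulate_race_structure(n_loci=200, n_per_site=8, seed=4)
        dm = pairwise_distance(ds, "squared_euclidean")
        coords, _ = classical_mds(dm, 2)
        races = hier.table.set_index("individual").loc[dm.individual_ids, "race"].to_numpy()
        # mean silhouette computed directly
        from scipy.spatial.distance import cdist

        D = cdist(coords, coords)
        sil = []
        for i in range(len(races)):
            same = races == races[i]
            a = D[i, same & (np.arange(len(races)) != i)].mean()
            b = min(D[i, races == r].mean() for r in set(races) if r != races[i])
            sil.append((b - a) / max(a, b))
        assert np.mean(sil) > 0


class TestPairwiseFst:
    def make_table(self, p1, p2, n=50):
        rows = []
        for i, (a, b) in enumerate(zip(p1, p2)):
            rows.append((f"L{i}", "pop1", n, 0, 1 - a, a, 0.0, "sqrt"))
            rows.append((f"L{i}", "pop2", n, 0, 1 - b, b, 0.0, "sqrt"))
        return pd.DataFrame(
            rows, columns=["locus", "population", "n", "k", "q_hat", "p_hat", "se", "method"]
        )

    def test_identical_frequencies_give_zero(self):
        p = np.linspace(0.1, 0.9, 20)
        table = self.make_table(p, p)
        res = pairwise_fst(table, None, None, "pop1", "pop2", n_perm=0)
        assert res.fst == pytest.approx(0.0, abs=1e-12)

    def test_fixed_opposite_alleles_give_one(self):
        table = self.make_table([1.0] * 10, [0.0] * 10)
        res = pairwise_fst(table, None, None, "pop1", "pop2", n_perm=0)
        assert res.fst == pytest.approx(1.0)

    def test_balding_nichols_recovery(self):
        """Simulation oracle: 1000 loci at F = 0.38 recovered within 0.05."""
        cfg = SimConfig(n_loci=1000, n_outliers=0, background_fst=0.38, seed=42)
        ds, _ = simulate_parental_populations(cfg)
        hier = two_pop_hierarchy(ds)
        table = dfm.allele_freq_table(ds, hier, method="bayes")
        res = pairwise_fst(table, ds, hier, "pop1", "pop2", n_perm=0)
        assert res.fst == pytest.approx(0.38, abs=0.05)

    def test_permutation_p_significant_for_structured_data(self):
        cfg = SimConfig(n_loci=200, n_outliers=0, background_fst=0.3,
                        n_per_population=(25, 25), seed=1)
        ds, _ = simulate_parental_populations(cfg)
        hier = two_pop_hierarchy(ds)
        table = dfm.allele_freq_table(ds, hier, method="sqrt")
        res = pairwise_fst(table, ds, hier, "pop1", "pop2", n_perm=99, method="sqrt", rng=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_invalid_n_perm(self):
        table = self.make_table([0.5], [0.5])
        with pytest.raises(ValueError):
            pairwise_fst(table, None, None, "pop1", "pop2", n_perm=-1)


class TestAmova:
    def test_identical_individuals_give_zero_components(self, small_hierarchy):
        pheno = np.tile(np.array([1, 0, 1, 0, 1], dtype=np.int8), (4, 1))
        ds = AFLPDataset(["a1", "a2", "b1", "b2"], [f"L{k}" for k in range(5)], pheno)
        res = amova(ds, small_hierarchy)
        assert np.allclose(res.table["sum_of_squares"], 0.0)

    def test_race_effect_dominates_with_fixed_differences(self):
        """Two races fixed for opposite alleles, no within-race structure."""
        rng = np.random.default_rng(0)
        n_half, L = 24, 60
        block = np.vstack(
            [np.tile([1] * L, (n_half, 1)), np.tile([0] * L, (n_half, 1))]
        ).astype(np.int8)
        noise = rng.random(block.shape) < 0.02
        block[noise] = 1 - block[noise]
        ids = [f"i{k}" for k in range(2 * n_half)]
        ds = AFLPDataset(ids, [f"L{k}" for k in range(L)], block)
        rows = []
        for k, ind in enumerate(ids):
            race = "r1" if k < n_half else "r2"
            pop = f"{race}_p{k % 2}"
            site = f"{pop}_s{k % 4 // 2}"
            rows.append((ind, site, pop, race))
        hier = PopulationHierarchy(
            pd.DataFrame(rows, columns=["individual", "site", "population", "race"])
        )
        res = amova(ds, hier)
        assert res.percents()["among_races"] > 90
        assert res.percents()["within_sites"] < 10

    def test_component_recovery_and_percent_sum(self):
        data, hier = simulate_nested_design(
            fractions=(0.25, 0.25, 0.25, 0.25), n_traits=200, seed=5
        )
        d2 = ((data[:, None, :] - data[None, :, :]) ** 2).sum(-1)
        dm = DistanceMatrix(hier.individuals, d2, "squared_euclidean")
        res = amova(dm, hier)
        pct = res.percents()
        assert pct.sum() == pytest.approx(100.0, abs=0.01)
        assert np.allclose(pct.to_numpy(), 25.0, atol=5.0)

    def test_permutation_p_uniformish_under_null(self):
        """Permutation p of a truly null site level is roughly uniform."""
        rng = np.random.default_rng(8)
        pvals = []
        for rep in range(60):
            data, hier = simulate_nested_design(
                fractions=(0.3, 0.2, 0.0, 0.5), n_traits=40,
                n_per_site=4, seed=1000 + rep,
            )
            d2 = ((data[:, None, :] - data[None, :, :]) ** 2).sum(-1)
            dm = DistanceMatrix(hier.individuals, d2, "squared_euclidean")
            res = amova(dm, hier, n_perm=49, rng=rep)
            pvals.append(
                res.table.set_index("level").loc["among_sites_within_pops", "p_value"]
            )
        from scipy import stats

        # discrete p-values from 49 permutations; compare with uniform loosely
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestHybridIndex:
    def make_freq_table(self, p1, p2):
        rows = []
        for i, (a, b) in enumerate(zip(p1, p2)):
            rows.append((f"L{i}", "pop1", 50, 0, 1 - a, a, 0.0, "sqrt"))
            rows.append((f"L{i}", "pop2", 50, 0, 1 - b, b, 0.0, "sqrt"))
        return pd.DataFrame(
            rows, columns=["locus", "population", "n", "k", "q_hat", "p_hat", "se", "method"]
        )

    def test_pure_parental_maps_to_q_one(self):
        L = 40
        table = self.make_freq_table([0.999] * L, [0.001] * L)
        ds = dataset_from_rows([[1] * L])
        [a] = hybrid_index(ds, table, "pop1", "pop2")
        assert a.Q == pytest.approx(1.0, abs=1e-3)

    def test_flat_likelihood_flagged_unidentifiable(self):
        table = self.make_freq_table([0.5] * 10, [0.5] * 10)
        ds = dataset_from_rows([[1, 0] * 5])
        [a] = hybrid_index(ds, table, "pop1", "pop2")
        assert not a.identifiable and np.isnan(a.Q)

    def test_simulated_hybrid_recovery(self):
        """True Q recovered with small RMSE from diagnostic loci."""
        cfg = SimConfig(n_loci=300, n_outliers=300, outliers_in_block=False,
                        n_per_population=(40, 40), n_hybrids=60, seed=21)
        ds, hier, truth = simulate_study(cfg)
        hybrids = hier.individuals_in("hybrid")
        table = dfm.allele_freq_table(ds, hier, method="bayes", exclude=hybrids)
        assignments = hybrid_index(ds, table, "pop1", "pop2", individuals=hybrids)
        q_hat = np.array([a.Q for a in assignments])
        rmse = np.sqrt(np.mean((q_hat - truth.true_Q.to_numpy()) ** 2))
        assert rmse <= 0.05

    def test_classification_boundary_is_strict(self):
        from aflpzone.structure_stats import HybridAssignment

        assignments = [
            HybridAssignment("x", 0.99, 0.0),
            HybridAssignment("y", 0.97, 0.0),
            HybridAssignment("z", 0.98, 0.0),
        ]
        nominal = {"x": "pop1", "y": "pop1", "z": "pop1"}
        classify_hybrids(assignments, nominal, "pop1", threshold=0.98)
        assert [a.is_hybrid for a in assignments] == [False, True, False]

    def test_nominal_toward_other_population(self):
        from aflpzone.structure_stats import HybridAssignment

        a = HybridAssignment("w", 0.01, 0.0)  # 99% toward pop2
        classify_hybrids([a], {"w": "pop2"}, "pop1")
        assert a.is_hybrid is False
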