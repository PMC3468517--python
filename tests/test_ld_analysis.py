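"""EM gametic disequilibrium for dominant loci and the LD contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aflpzone.aflp_io import AFLPDataset
from aflpzone.ld_analysis import (
    afd_product,
    closed_form_ld_dominant,
    compare_outlier_vs_neutral_ld,
    em_ld_dominant,
    grid_ld_dominant,
    max_pairwise_d,
    pairwise_ld_matrix,
    phenotype_counts,
)


def equilibrium_counts(p_a=0.5, p_b=0.5, n=160):
    """Phenotype counts exactly proportional to two-locus equilibrium."""
    q_a2, q_b2 = (1 - p_a) ** 2, (1 - p_b) ** 2
    probs = np.array(
        [(1 - q_a2) * (1 - q_b2), (1 - q_a2) * q_b2, q_a2 * (1 - q_b2), q_a2 * q_b2]
    )
    return tuple(np.round(probs * n).astype(int))


def random_table(rng, n_max=200):
    """Multinomial phenotype table from random haplotype frequencies."""
    while True:
        f = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
        qa, qb, fab = f[2] + f[3], f[1] + f[3], f[3]
        p = np.array(
            [1 - qa**2 - qb**2 + fab**2, qb**2 - fab**2, qa**2 - fab**2, fab**2]
        )
        n = int(rng.integers(20, n_max + 1))
        c = rng.multinomial(n, p)
        if (c[1] + c[3]) not in (0, n) and (c[2] + c[3]) not in (0, n):
            return tuple(int(v) for v in c)


class TestAnalyticBound:
    def test_maximum_d_over_simplex_is_quarter(self):
        """Perfect coupling of two loci at frequency 1/2 attains D = 0.25."""
        assert max_pairwise_d() == 0.25


class TestClosedForm:
    def test_complete_association(self):
        est = closed_form_ld_dominant((75, 0, 0, 25))
        assert est.frequencies == pytest.approx([0.5, 0.0, 0.0, 0.5])
        assert est.D == 0.25

    def test_equilibrium_gives_zero_d(self):
        est = closed_form_ld_dominant(equilibrium_counts())
        assert est is not None and est.D == pytest.approx(0.0, abs=1e-12)

    def test_boundary_table_signalled(self):
        # strong repulsion: moment f_AB = 1 - q_A - q_B + f_ab < 0
        assert closed_form_ld_dominant((0, 50, 50, 0)) is None


class TestEMDominant:
    def test_complete_association_exact(self):
        est = em_ld_dominant((75, 0, 0, 25))
        assert est.D == 0.25 and est.converged

    def test_equilibrium_gives_zero(self):
        est = em_ld_dominant(equilibrium_counts())
        assert est.D == pytest.approx(0.0, abs=1e-6)

    def test_em_matches_closed_form_on_interior_tables(self, rng):
        for _ in range(50):
            counts = random_table(rng)
            cf = closed_form_ld_dominant(*[counts])
            if cf is None:
                continue
            # EM converges linearly; the iterate tracks the exact moment
            # solution to well below the grid-oracle band
            em = em_ld_dominant(counts, polish=False, tol=1e-10)
            assert em.D == pytest.approx(cf.D, abs=5e-4)

    def test_em_beats_closed_form_likelihood_on_boundary(self, rng):
        found = 0
        for _ in range(300):
            counts = random_table(rng, n_max=60)
            if closed_form_ld_dominant(counts) is not None:
                continue
            found += 1
            em = em_ld_dominant(counts)
            gr = grid_ld_dominant(counts)
            assert em.loglik >= gr.loglik - 1e-6
            if found >= 10:
                break
        assert found > 0

    def test_em_agrees_with_grid_oracle(self, rng):
        for _ in range(15):
            counts = random_table(rng)
            em = em_ld_dominant(counts)
            gr = grid_ld_dominant(counts)
            assert abs(em.D - gr.D) <= 1e-3

    @given(st.lists(st.integers(0, 80), min_size=4, max_size=4))
    def test_simplex_and_bound_invariants(self, counts):
        n = sum(counts)
        counts = tuple(counts)
        if n == 0:
            with pytest.raises(ValueError):
                em_ld_dominant(counts)
            return
        if (counts[1] + counts[3]) in (0, n) or (counts[2] + counts[3]) in (0, n):
            return  # monomorphic: not a valid LD table
        est = em_ld_dominant(counts)
        f = est.frequencies
        assert np.all(f >= -1e-12) and f.sum() == pytest.approx(1.0)
        assert abs(est.D) <= 0.25 + 1e-12
        if est.D >= 0:
            bound = min(est.p_A * (1 - est.p_B), (1 - est.p_A) * est.p_B)
        else:
            bound = min(est.p_A * est.p_B, (1 - est.p_A) * (1 - est.p_B))
        assert abs(est.D) <= bound + 1e-9

    def test_swap_invariance(self, rng):
        for _ in range(20):
            n_pp, n_pa, n_ap, n_aa = random_table(rng)
            a = em_ld_dominant((n_pp, n_pa, n_ap, n_aa))
            b = em_ld_dominant((n_pp, n_ap, n_pa, n_aa))  # loci swapped
            assert a.D == pytest.approx(b.D, abs=1e-9)


class TestPairwiseMatrix:
    def test_pairs_below_min_n_skipped_and_missing_deleted(self, rng):
        pheno = rng.choice([0, 1], size=(12, 3)).astype(np.int8)
        pheno[:, 2] = -1  # entirely missing locus
        pheno[0, 2] = 1
        ds = AFLPDataset([f"i{k}" for k in range(12)], ["A", "B", "C"], pheno)
        ests = pairwise_ld_matrix(ds, min_n=10)
        pairs = {(e.locus1, e.locus2) for e in ests}
        assert ("A", "C") not in pairs and ("B", "C") not in pairs

    def test_single_locus_rejected(self, rng):
        ds = AFLPDataset(["i0"], ["A"], np.array([[1]], dtype=np.int8))
        with pytest.raises(ValueError):
            pairwise_ld_matrix(ds)


class TestAFDProduct:
    def make_table(self, p, q, r, s):
        rows = [
            ("L1", "pop1", 50, 0, 1 - p, p, 0.0, "sqrt"),
            ("L1", "pop2", 50, 0, 1 - q, q, 0.0, "sqrt"),
            ("L2", "pop1", 50, 0, 1 - r, r, 0.0, "sqrt"),
            ("L2", "pop2", 50, 0, 1 - s, s, 0.0, "sqrt"),
        ]
        return pd.DataFrame(
            rows, columns=["locus", "population", "n", "k", "q_hat", "p_hat", "se", "method"]
        )

    def test_same_population_fixation_is_plus_one(self):
        res = afd_product(self.make_table(1, 0, 1, 0), "pop1", "pop2", "L1", "L2")
        assert res.product == 1.0 and res.class_label == "same_pop_fixed_like"

    def test_opposite_population_fixation_is_minus_one(self):
        res = afd_product(self.make_table(1, 0, 0, 1), "pop1", "pop2", "L1", "L2")
        assert res.product == -1.0 and res.class_label == "opposite_pop_fixed_like"

    def test_equal_frequencies_are_intermediate(self):
        res = afd_product(self.make_table(0.4, 0.4, 1, 0), "pop1", "pop2", "L1", "L2")
        assert res.product == 0.0 and res.class_label == "intermediate"


class TestComparison:
    @staticmethod
    def welch(x, y):
        """Textbook Welch t and df for the one-tailed arithmetic oracle."""
        x, y = np.asarray(x, float), np.asarray(y, float)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        return t, df

    def build(self, out_vals, neut_vals, product=0.9):
        from aflpzone.ld_analysis import AFDProduct, LDEstimate

        ests, prods = [], []
        idx = 0
        # outlier pairs come from outlier loci O*, neutral from N*
        for v in out_vals:
            e = LDEstimate(f"O{idx}", f"O{idx + 1}", 0.25, 0.25, 0.25, 0.25, n=50)
            e.f_AB = 0.25 + v  # encode target D via f_AB * f_ab - f_Ab * f_aB
            ests.append(e)
            prods.append(AFDProduct(e.locus1, e.locus2, product, "same_pop_fixed_like"))
            idx += 2
        for v in neut_vals:
            e = LDEstimate(f"N{idx}", f"N{idx + 1}", 0.25, 0.25, 0.25, 0.25, n=50)
            e.f_AB = 0.25 + v
            ests.append(e)
            prods.append(AFDProduct(e.locus1, e.locus2, product, "same_pop_fixed_like"))
            idx += 2
        outlier_set = {e.locus1 for e in ests if e.locus1.startswith("O")}
        outlier_set |= {e.locus2 for e in ests if e.locus2.startswith("O")}
        return ests, prods, outlier_set

    def test_matches_textbook_welch_formula(self):
        out_vals = [0.02, 0.05, 0.08]
        neut_vals = [0.01, 0.02, 0.00]
        ests, prods, outliers = self.build(out_vals, neut_vals)
        res = compare_outlier_vs_neutral_ld(ests, prods, outliers)
        d_out = [e.D for e in ests[:3]]
        d_neut = [e.D for e in ests[3:]]
        t, df = self.welch(d_out, d_neut)
        assert res.positive.t == pytest.approx(t)
        assert res.positive.df == pytest.approx(df)
        from scipy import stats

        assert res.positive.p == pytest.approx(stats.t.sf(t, df))

    def test_insufficient_tail_flagged_unavailable(self):
        ests, prods, outliers = self.build([0.02], [0.01, 0.03])
        res = compare_outlier_vs_neutral_ld(ests, prods, outliers)
        assert res.positive is None and res.negative is None

    def test_mixed_pairs_excluded(self):
        from aflpzone.ld_analysis import AFDProduct, LDEstimate

        ests, prods, outliers = self.build([0.02, 0.04], [0.01, 0.02])
        mixed = LDEstimate("O0", "Nx", 0.5, 0.0, 0.0, 0.5, n=50)
        ests.append(mixed)
        prods.append(AFDProduct("O0", "Nx", 0.95, "same_pop_fixed_like"))
        res = compare_outlier_vs_neutral_ld(ests, prods, outliers)
        assert res.positive.n_outlier_pairs == 2 and res.positive.n_neutral_pairs == 2

    def test_null_calibration(self, rng):
        """Outlier and neutral LD from the same distribution: one-tailed p
        roughly uniform (rejection fraction near 0.05)."""
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            out_vals = rng.normal(0.05, 0.02, size=8)
            neut_vals = rng.normal(0.05, 0.02, size=15)
            ests, prods, outliers = self.build(list(out_vals), list(neut_vals))
            res = compare_outlier_vs_neutral_ld(ests, prods, outliers)
            rejections += res.positive.p < 0.05
        assert 0.02 < rejections / n_sims < 0.09

    def test_paper_scale_shift_detected(self, rng):
        """A +0.03 shift at the study's group sizes (21 outlier pairs vs a
        comparable neutral pool) is detected in most replicates."""
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            out_vals = rng.normal(0.142, 0.03, size=21)
            neut_vals = rng.normal(0.113, 0.03, size=40)
            ests, prods, outliers = self.build(list(out_vals), list(neut_vals))
            res = compare_outlier_vs_neutral_ld(ests, prods, outliers)
            hits += res.positive.p < 0.05
        assert hits / n_sims > 0.5
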