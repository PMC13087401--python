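import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twascal as tc
from twascal.errors import DegenerateInputError, DomainError, RankError
from twascal.phi import GridPoint, InflationGrid, read_phi_table, write_phi_table


def synthetic_grid(slope, intercept=1.0, noise_sd=0.0, seed=0, mediator="g"):
    rng = np.random.default_rng(seed)
    points = []
    for n in (500, 1000, 2000, 4000):
        for h2 in (0.0, 0.25, 0.5, 1.0):
            x = n * h2
            y = intercept + slope * x + rng.normal(scale=noise_sd)
            points.append(GridPoint(n, h2, y, noise_sd, 0))
    return InflationGrid(points=points, n_replicates=100, mediator_id=mediator)


class TestRunInflationGrid:
    def test_grid_shape_seven_by_five(self, genotypes_small, mediators_small):
        ns = [30, 50, 80, 100, 120, 150, 200]
        h2s = [0.0, 0.25, 0.5, 0.75, 1.0]
        grid = tc.run_inflation_grid(
            genotypes_small, mediators_small[0], ns, h2s, n_replicates=3, seed=1
        )
        assert len(grid.points) == 35
        assert len({(p.n, p.h2_delta) for p in grid.points}) == 35

    def test_zero_heritability_cells_near_one(self, genotypes_1k, mediator_1k):
        grid = tc.run_inflation_grid(
            genotypes_1k, mediator_1k, [500, 1000], [0.0], n_replicates=400, seed=2
        )
        for p in grid.points:
            assert abs(p.mean_z2 - 1.0) < 4 * np.sqrt(2 / 400)

    def test_oversized_n_rejected(self, genotypes_small, mediators_small):
        with pytest.raises(DomainError):
            tc.run_inflation_grid(
                genotypes_small, mediators_small[0], [2 * genotypes_small.n_samples],
                [0.5], n_replicates=2, seed=0,
            )

    def test_cells_reproducible(self, genotypes_small, mediators_small):
        a = tc.run_inflation_grid(
            genotypes_small, mediators_small[0], [100], [0.5], n_replicates=5, seed=3
        )
        b = tc.run_inflation_grid(
            genotypes_small, mediators_small[0], [100], [0.5], n_replicates=5, seed=3
        )
        assert a.points == b.points


class TestEstimatePhi:
    def test_perfect_linear_grid_recovered_exactly(self):
        est = tc.estimate_phi(synthetic_grid(slope=3e-5))
        assert est.slope == pytest.approx(3e-5, rel=1e-9)
        assert est.slope_se == pytest.approx(0.0, abs=1e-12)
        assert est.phi == pytest.approx(3e-5, rel=1e-9)
        assert est.intercept == pytest.approx(1.0, rel=1e-9)
        assert est.r2 == pytest.approx(1.0)

    def test_single_cell_grid_rejected(self):
        grid = InflationGrid(
            points=[GridPoint(1000, 0.5, 1.5, 0.1, 0)], n_replicates=10, mediator_id="g"
        )
        with pytest.raises(RankError):
            tc.estimate_phi(grid)

    @given(st.integers(0, 2**31 - 1))
    def test_one_se_adjustment_is_conservative(self, seed):
        est = tc.estimate_phi(synthetic_grid(slope=2e-5, noise_sd=0.05, seed=seed))
        assert est.phi >= est.slope
        assert est.phi >= 0.0

    def test_planted_slope_recovered_within_two_se(self):
        hits = 0
        for seed in range(20):
            est = tc.estimate_phi(synthetic_grid(slope=5e-5, noise_sd=0.03, seed=seed))
            if abs(est.slope - 5e-5) <= 2 * est.slope_se:
                hits += 1
        assert hits >= 17  # ~95% coverage, allow slack

    def test_simulation_grid_recovers_independent_snp_slope(self, genotypes_1k, mediator_1k):
        """End to end: grid simulation + regression recovers Phi ~= 1/M."""
        grid = tc.run_inflation_grid(
            genotypes_1k, mediator_1k, [500, 1000], [0.0, 0.5, 1.0],
            n_replicates=400, seed=4,
        )
        est = tc.estimate_phi(grid)
        assert abs(est.slope - 1 / 999) < 2 * est.slope_se + 2e-4


class TestTheoreticalPhi:
    def test_identity_ld_gives_one_over_m(self):
        rng = np.random.default_rng(0)
        for m in (3, 10, 50):
            w = rng.normal(size=m)
            assert tc.theoretical_phi(w, np.eye(m), m) == pytest.approx(1 / m, abs=1e-14)

    def test_two_snp_hand_algebra(self):
        for r in (0.0, 0.3, 0.9, -0.6):
            sigma = np.array([[1.0, r], [r, 1.0]])
            got = tc.theoretical_phi(np.array([1.0, 0.0]), sigma, 2)
            assert got == pytest.approx((1 + r * r) / 2, abs=1e-12)

    def test_weightset_alignment_zero_fills_missing(self):
        ld = tc.LDMatrix(np.eye(3), variant_ids=["a", "b", "c"])
        w = tc.WeightSet(
            mediator_id="g",
            variant_ids=np.array(["b", "zzz"], dtype=object),
            ref_allele=np.array(["A", "A"], dtype=object),
            eff_allele=np.array(["G", "G"], dtype=object),
            weights=np.array([2.0, 5.0]),
        )
        assert tc.theoretical_phi(w, ld, 3) == pytest.approx(1 / 3)

    def test_zero_weights_rejected(self):
        with pytest.raises(DegenerateInputError):
            tc.theoretical_phi(np.zeros(4), np.eye(4), 4)

    def test_conditional_oracle_predicts_simulated_inflation(self, genotypes_1k, mediator_1k):
        """Eq-style slope evaluated on the realized sample LD predicts the
        simulated mean Z^2 cell more sharply than the population value."""
        X = genotypes_1k.dosages
        n, m = X.shape
        sigma_hat = X.T @ X / n
        w = tc.simulate_true_weights(999, 1.0, seed=12, template=genotypes_1k).weights
        phi_hat = tc.theoretical_phi(w, sigma_hat, m)
        s = tc.batch_null_associations(
            genotypes_1k, mediator_1k, tc.NullTraitSpec(1.0, seed=13), 1000
        )
        predicted = 1 + 1.0 * (n * phi_hat - 1)  # conditional on X: 1 + h2 (n phi - 1)
        assert abs(s.mean_z2 - predicted) < 4 * s.se_mean_z2


class TestExpectedZ2:
    def test_no_inflation_limit(self):
        for n, h2 in ((10, 0.1), (100000, 1.0)):
            assert tc.expected_z2(n, h2, 0.0) == 1.0

    def test_real_data_scale_worked_example(self):
        assert tc.expected_z2(100_000, 0.5, 4.2e-5) == pytest.approx(3.1)

    def test_negative_phi_rejected(self):
        with pytest.raises(DomainError):
            tc.expected_z2(100, 0.5, -1e-5)

    def test_monotone_in_each_argument(self):
        base = tc.expected_z2(1000, 0.5, 2e-5)
        assert tc.expected_z2(2000, 0.5, 2e-5) >= base
        assert tc.expected_z2(1000, 0.75, 2e-5) >= base
        assert tc.expected_z2(1000, 0.5, 4e-5) >= base


class TestExpectedZ2Alt:
    @given(
        st.integers(100, 10**6),
        st.floats(0, 1),
        st.floats(0, 1e-4),
        st.floats(0, 1),
    )
    def test_reduces_to_null_formula_when_h2gene_zero(self, n, h2, phi, tau2):
        """Prediction precision tau2 has no effect under the null."""
        inp = tc.AltExpectationInput(n=n, h2_delta=h2, phi=phi, tau2=tau2, h2_gene=0.0)
        assert tc.expected_z2_alt(inp) == tc.expected_z2(n, h2, phi)

    def test_hand_arithmetic_power_term(self):
        inp = tc.AltExpectationInput(n=1000, h2_delta=0.0, phi=7e-5, tau2=1.0, h2_gene=0.05)
        assert tc.expected_z2_alt(inp) == pytest.approx(1 + 1000 * 0.05 / 0.95, rel=1e-12)

    def test_singular_denominator_rejected(self):
        with pytest.raises(DomainError):
            tc.AltExpectationInput(n=1000, h2_delta=0.5, phi=1e-5, tau2=1.0, h2_gene=1.0)

    def test_lower_precision_lowers_power_term(self):
        hi = tc.expected_z2_alt(
            tc.AltExpectationInput(n=10_000, h2_delta=0.5, phi=2e-5, tau2=0.9, h2_gene=0.05)
        )
        lo = tc.expected_z2_alt(
            tc.AltExpectationInput(n=10_000, h2_delta=0.5, phi=2e-5, tau2=0.3, h2_gene=0.05)
        )
        assert hi > lo


class TestPhiRobustnessToSparsity:
    def test_phi_stable_across_prop_nonzero(self, genotypes_1k, mediator_1k):
        """Slope estimates at pi in {0.3, 0.9} stay within 2 combined SEs of
        the pi=1 estimate (the smaller-pi one may drift slightly low)."""
        base = tc.estimate_phi(
            tc.run_inflation_grid(
                genotypes_1k, mediator_1k, [500, 1000], [0.0, 0.5, 1.0],
                n_replicates=300, seed=5, prop_nonzero=1.0,
            )
        )
        for prop in (0.3, 0.9):
            est = tc.estimate_phi(
                tc.run_inflation_grid(
                    genotypes_1k, mediator_1k, [500, 1000], [0.0, 0.5, 1.0],
                    n_replicates=300, seed=5, prop_nonzero=prop,
                )
            )
            combined = np.hypot(base.slope_se, est.slope_se)
            assert abs(est.slope - base.slope) < 2 * combined + 1e-4


class TestPhiTableIO:
    def test_roundtrip(self, tmp_path):
        est = tc.estimate_phi(synthetic_grid(slope=2e-5, noise_sd=0.01, seed=1))
        path = tmp_path / "phi.tsv"
        write_phi_table([est], path)
        back = read_phi_table(path)
        assert back["g"].phi == pytest.approx(est.phi)
        assert back["g"].slope == pytest.approx(est.slope)
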