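"""Mechanism simulator: conservation, branching, noise model, dataset emitter."""

import numpy as np
import pandas as pd
import pytest

import ligfid as lf
from ligfid.simulate import (
    BAND_COLUMNS,
    CANONICAL,
    MG_GRID_MM,
    Condition,
    Design,
    MechanismParams,
)
from conftest import (
    branching_abort_probability,
    longtime_abort_fraction,
    random_mechanism,
)

TIMES = np.array([5.0, 15.0, 30.0, 60.0, 120.0, 300.0, 900.0])


def test_mass_conservation_random_schemes(rng):
    """Noiseless trajectories conserve total DNA across S, I, P pools."""
    for _ in range(10):
        p = random_mechanism(rng)
        tc = lf.simulate_mechanism(p, TIMES)
        assert np.max(np.abs(tc.fractions.sum(axis=1) - 1.0)) <= 1e-8


def test_product_fraction_monotone_noiseless(rng):
    """Sealed product only accumulates in the deterministic trajectory."""
    for _ in range(5):
        p = random_mechanism(rng)
        tc = lf.simulate_mechanism(p, TIMES)
        assert np.all(np.diff(tc.f_p) >= -1e-12)
        assert np.all((tc.fractions >= -1e-12) & (tc.fractions <= 1 + 1e-12))


def test_no_abortive_branch_seals_everything(wt_canonical):
    """With zero dissociation from the intermediate, all DNA ends sealed."""
    p = wt_canonical.replace(k_diss=0.0, enzyme_total=200.0, dna_total=50.0)
    tc = lf.simulate_mechanism(p, np.array([20000.0]))
    assert tc.f_i[-1] == pytest.approx(0.0, abs=1e-8)
    assert tc.f_p[-1] == pytest.approx(1.0, abs=1e-8)


def test_mg_activation_halves_at_k_mg(wt_canonical):
    """The step-3 effective rate at [Mg] = K_mg is exactly half maximal."""
    p = wt_canonical.replace(mg_free=wt_canonical.K_mg_step3)
    assert p.k_seal == pytest.approx(p.k_seal_max / 2, rel=1e-15)
    assert lf.mg_activation(1e9, 1.1) == pytest.approx(1.0, abs=1e-6)


def test_branching_matches_equal_exit_rate_oracle():
    """Equal post-transfer exit rates with a dominant open route: simulator
    long-time abortive fraction matches the analytic branching probability."""
    p = MechanismParams(
        k_bind=0.2, k_open=50.0, k_close=0.5, k_diss=2.0,
        k_transfer_max=10.0, k_seal_max=2.0, K_mg_step2=0.1, K_mg_step3=0.5,
        enzyme_total=200.0, dna_total=50.0, mg_free=1e6,  # Mg-saturated: k_seal = k_diss
    )
    q_oracle = branching_abort_probability(p)
    q_sim = longtime_abort_fraction(p)
    assert q_sim == pytest.approx(q_oracle, abs=1e-6)


def test_branching_matches_rate_matrix_oracle_random(rng):
    """Long-time abortive/sealed split equals absorbing-state probabilities
    of the rate matrix across random parameter sets."""
    for _ in range(20):
        p = random_mechanism(rng)
        q_oracle = branching_abort_probability(p)
        q_sim = longtime_abort_fraction(p)
        assert q_sim == pytest.approx(q_oracle, rel=1e-5, abs=1e-8)


def test_abortive_fraction_monotone_in_k_diss_and_mg(wt_canonical):
    """More intermediate dissociation, or less Mg²⁺, means more abortive ligation."""
    base = wt_canonical.replace(enzyme_total=200.0, dna_total=50.0)
    qs = [
        longtime_abort_fraction(base.replace(k_diss=kd))
        for kd in (0.1, 0.37, 1.0, 3.0, 10.0)
    ]
    assert np.all(np.diff(qs) > 0)
    # K_mg_step3 > K_mg_step2 for these presets: sealing slows first
    qs_mg = [longtime_abort_fraction(base.replace(mg_free=mg)) for mg in (5.0, 1.0, 0.3, 0.1)]
    assert np.all(np.diff(qs_mg) > 0)


def test_invalid_parameters_rejected(wt_canonical):
    with pytest.raises(ValueError):
        wt_canonical.replace(k_open=-1.0)
    with pytest.raises(ValueError):
        wt_canonical.replace(K_mg_step3=0.0)
    with pytest.raises(ValueError):
        lf.simulate_mechanism(wt_canonical, np.array([10.0, 5.0]))


class TestGelNoise:
    def test_zero_sigma_is_identity(self, wt_canonical):
        tc = lf.simulate_mechanism(wt_canonical, TIMES)
        out = lf.add_gel_noise(tc, 0.0, seed=1)
        assert np.array_equal(out.fractions, tc.fractions)

    def test_fixed_seed_reproducible(self, wt_canonical):
        tc = lf.simulate_mechanism(wt_canonical, TIMES)
        a = lf.add_gel_noise(tc, 0.05, seed=42)
        b = lf.add_gel_noise(tc, 0.05, seed=42)
        assert np.array_equal(a.fractions, b.fractions)
        c = lf.add_gel_noise(tc, 0.05, seed=43)
        assert not np.array_equal(a.fractions, c.fractions)

    def test_lanes_renormalized(self, wt_canonical):
        tc = lf.simulate_mechanism(wt_canonical, TIMES)
        out = lf.add_gel_noise(tc, 0.1, seed=7)
        assert np.allclose(out.fractions.sum(axis=1), 1.0)
        assert np.all(out.fractions >= 0)

    def test_post_renormalization_sd_matches_monte_carlo(self):
        """1000 replicate lanes of a fixed triple: per-band SD within 15% of a
        large-sample Monte-Carlo estimate of the clip-and-renormalize model."""
        truth = np.array([0.6, 0.3, 0.1])
        sigma = 0.02
        tc = lf.SimulatedTimeCourse(
            times=np.arange(1.0, 1001.0), fractions=np.tile(truth, (1000, 1))
        )
        sds = lf.add_gel_noise(tc, sigma, seed=11).fractions.std(axis=0)

        rng = np.random.default_rng(999)
        big = np.clip(truth + rng.normal(0, sigma, size=(200_000, 3)), 0, None)
        big /= big.sum(axis=1, keepdims=True)
        sds_mc = big.std(axis=0)
        assert np.all(np.abs(sds / sds_mc - 1.0) < 0.15)


class TestGenerateDataset:
    def test_single_cell_sums_to_total_signal(self):
        cond = Condition("WT", CANONICAL, 1.0, 1000.0, 0.2, 1.0)
        df = lf.generate_dataset(
            Design((cond,), times=(60.0,), replicates=1), noise_sigma=0.0, seed=0
        )
        assert len(df) == 1
        row = df.iloc[0]
        total = row.intensity_s + row.intensity_i + row.intensity_p
        assert total == pytest.approx(1000.0, rel=1e-9)
        assert list(df.columns) == BAND_COLUMNS

    def test_replicate_count(self):
        cond = Condition("WT", CANONICAL, 1.0, 1000.0, 0.2, 1.0)
        df = lf.generate_dataset(
            Design((cond,), times=(30.0, 60.0), replicates=3), noise_sigma=0.02, seed=0
        )
        counts = df.groupby(["mg_free_mM", "time_s"]).size()
        assert (counts == 3).all()

    def test_missing_condition_parameters_raise(self):
        cond = Condition("E346A", "weird", 1.0, 1000.0, 0.2, 1.0)
        with pytest.raises(KeyError):
            lf.generate_dataset(Design((cond,), times=(60.0,)), seed=0)
        with pytest.raises(KeyError):
            lf.generate_dataset(
                Design((cond,), times=(60.0,)), params_by_condition={}, seed=0
            )

    def test_seed_reproducibility(self):
        cond = Condition("WT", CANONICAL, 1.0, 1000.0, 0.2, 0.5)
        design = Design((cond,), times=(30.0, 60.0, 120.0), replicates=2)
        a = lf.generate_dataset(design, noise_sigma=0.02, seed=5)
        b = lf.generate_dataset(design, noise_sigma=0.02, seed=5)
        pd.testing.assert_frame_equal(a, b)


def test_hyperbolic_generator_linear_in_window():
    """The phenomenological generator is exactly linear inside the rate window
    and its intermediate band reflects the requested abortive partitioning."""
    df = lf.generate_hyperbolic_dataset(
        [0.5, 2.0], k_cat=1.0, k_mg_mM=1.0, f_abort=0.2, noise_sigma=0.0, seed=0,
        replicates=1,
    )
    for mg, grp in df.groupby("mg_free_mM"):
        fp = grp.intensity_p / (grp.intensity_s + grp.intensity_i + grp.intensity_p)
        slope = np.polyfit(grp.time_s, fp, 1)[0]
        expected = (1.0 * mg / (1.0 + mg)) * 1.0 / 1000.0
        assert slope == pytest.approx(expected, rel=1e-9)
        fab = grp.intensity_i.sum() / (grp.intensity_i.sum() + grp.intensity_p.sum())
        assert fab == pytest.approx(0.2, rel=1e-9)


def test_ssa_branching_consistent_with_ode(rng):
    """Stochastic backend reproduces the deterministic abortive fraction
    within Monte-Carlo error."""
    p = MechanismParams(
        k_bind=0.2, k_open=2.0, k_close=5.0, k_diss=2.0,
        k_transfer_max=20.0, k_seal_max=3.0, K_mg_step2=0.1, K_mg_step3=1.0,
        enzyme_total=100.0, dna_total=50.0, mg_free=1.0,
    )
    q_ode = longtime_abort_fraction(p)
    tc = lf.simulate_mechanism_ssa(p, np.array([500.0]), n_dna=4000, seed=3)
    q_ssa = tc.f_i[-1] / (tc.f_i[-1] + tc.f_p[-1])
    # binomial MC error at n=4000 is ~0.008; allow 4 sigma
    assert q_ssa == pytest.approx(q_ode, abs=0.032)
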