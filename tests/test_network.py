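"""Core ODE network: conservation, MOMP detection, binding equilibria."""
import numpy as np
import pytest

from mompdose import (ABT199, CRC0076, DrugSpec, KineticParameters, NO_DRUG,
                      ProteinProfile, StressInput, ValidationError,
                      build_initial_state, detect_momp,
                      equilibrium_free_fractions, simulate_network)
from mompdose.network import IDX, TrajectoryResult, family_totals
from mompdose.synthetic import random_profile


def _simulate(profile, dose, params, drug=NO_DRUG, **kw):
    stress = StressInput.for_profile(dose, profile)
    return simulate_network(build_initial_state(profile, drug, stress),
                            params, drug, **kw)


class TestSimulation:
    def test_zero_stress_means_no_pores(self, default_params):
        traj = _simulate(CRC0076, 0.0, default_params)
        assert np.all(traj.pore_fraction == 0.0)
        assert traj.momp_time is None

    def test_unopposed_effectors_reach_momp(self, default_params):
        """With no anti-apoptotic proteins a large activator bolus must
        trigger MOMP before the horizon; the crossing time agrees with
        an independent fixed-step integration of the reduced system."""
        profile = ProteinProfile("bare", bak=500.0, bax=500.0, bcl2=0.0,
                                 bclxl=0.0, mcl1=0.0)
        traj = _simulate(profile, 1e4, default_params)
        assert traj.momp_time is not None
        assert traj.momp_time < default_params.horizon

        # reduced ODE: activator decay, catalytic activation, dimerisation.
        # BAX and BAK are symmetric 500 nM pools; track one and double its
        # pore count.
        p = default_params
        a, bi, ba, pores = 8e3, 500.0, 0.0, 0.0
        def rhs(a, bi, ba, pores):
            return (-p.k_deg_bh3 * a,
                    -p.k_act * a * bi,
                    p.k_act * a * bi - 2 * p.k_oligo * ba ** 2,
                    p.k_oligo * ba ** 2)
        h = 1e-4
        t, t_momp = 0.0, None
        while t < p.horizon:
            k1 = rhs(a, bi, ba, pores)
            k2 = rhs(*(v + 0.5 * h * k for v, k in zip((a, bi, ba, pores), k1)))
            k3 = rhs(*(v + 0.5 * h * k for v, k in zip((a, bi, ba, pores), k2)))
            k4 = rhs(*(v + h * k for v, k in zip((a, bi, ba, pores), k3)))
            a, bi, ba, pores = (v + h / 6 * (x1 + 2 * x2 + 2 * x3 + x4)
                                for v, x1, x2, x3, x4
                                in zip((a, bi, ba, pores), k1, k2, k3, k4))
            t += h
            if 2 * (2 * pores) / 1000.0 >= p.momp_threshold:
                t_momp = t
                break
        assert t_momp is not None
        assert traj.momp_time == pytest.approx(t_momp, abs=2e-3)

    def test_family_mass_conserved(self, default_params, rng):
        for i in range(10):
            profile = random_profile(rng, f"c{i}",
                                     effector_range=(100.0, 2000.0),
                                     anti_range=(100.0, 3000.0))
            dose = float(rng.uniform(0.0, 5000.0))
            drug = ABT199.at_dose(float(rng.uniform(0.0, 10000.0)))
            traj = _simulate(profile, dose, default_params, drug)
            assert traj.conservation_error <= 1e-6

    def test_no_species_goes_negative(self, default_params, rng):
        profile = random_profile(rng, "neg", effector_range=(100.0, 1000.0),
                                 anti_range=(100.0, 1000.0))
        traj = _simulate(profile, 2000.0, default_params,
                         ABT199.at_dose(500.0))
        assert traj.states.min() >= -1e-9

    def test_pore_fraction_monotone(self, default_params, rng):
        profile = random_profile(rng, "mono", effector_range=(200.0, 800.0),
                                 anti_range=(10.0, 200.0))
        traj = _simulate(profile, 3000.0, default_params)
        assert np.all(np.diff(traj.pore_fraction) >= -1e-12)

    def test_drug_neutrality_at_infinite_kd(self, default_params):
        """A drug with 1e12 nM Kds must leave the trajectory unchanged."""
        inert = DrugSpec("inert", 1e12, 1e12, 1e12, dose=10000.0)
        t_eval = np.linspace(0.0, default_params.horizon, 50)
        a = _simulate(CRC0076, 3000.0, default_params, NO_DRUG, t_eval=t_eval)
        b = _simulate(CRC0076, 3000.0, default_params, inert, t_eval=t_eval)
        drug_cols = [i for n, i in IDX.items() if "drug" in n]
        protein_cols = [i for i in range(len(IDX)) if i not in drug_cols]
        assert np.allclose(a.states[:, protein_cols],
                           b.states[:, protein_cols], atol=1e-5)


class TestDetectMomp:
    def _linear_traj(self, slope=0.02, t_end=12.0, n=25):
        t = np.linspace(0.0, t_end, n)
        pf = np.minimum(1.0, slope * t)
        states = np.zeros((n, len(IDX)))
        return TrajectoryResult(t, states, pf, None, 0.1, 1.0, 0.0, sol=None)

    def test_flat_trajectory_has_no_momp(self):
        traj = self._linear_traj(slope=0.0)
        assert detect_momp(traj, 0.1) is None

    def test_linear_crossing_located_exactly(self):
        traj = self._linear_traj(slope=0.02)
        assert detect_momp(traj, 0.1) == pytest.approx(5.0, abs=1e-9)

    def test_threshold_validated(self):
        traj = self._linear_traj()
        with pytest.raises(ValidationError):
            detect_momp(traj, 1.5)

    def test_matches_dense_grid_scan(self, rng):
        """Root-found crossing agrees with a 1e4-point grid scan."""
        for _ in range(5):
            t = np.linspace(0.0, 12.0, 40)
            increments = rng.uniform(0.0, 0.02, len(t) - 1)
            pf = np.concatenate([[0.0], np.cumsum(increments)])
            states = np.zeros((len(t), len(IDX)))
            traj = TrajectoryResult(t, states, pf, None, 0.1, 1.0, 0.0,
                                    sol=None)
            threshold = float(rng.uniform(0.05, pf.max() * 0.9))
            found = detect_momp(traj, threshold)
            fine = np.linspace(0.0, 12.0, 10_000)
            fine_pf = np.interp(fine, t, pf)
            above = fine[fine_pf >= threshold]
            expected = float(above[0]) if above.size else None
            assert found == pytest.approx(expected, abs=1e-3)


class TestEquilibriumFreeFractions:
    def test_zero_dose_leaves_everything_free(self):
        free = equilibrium_free_fractions(CRC0076, ABT199.at_dose(0.0))
        assert free["bcl2"] == pytest.approx(CRC0076.bcl2, rel=1e-9)
        assert free["bclxl"] == pytest.approx(CRC0076.bclxl, rel=1e-9)

    def test_single_site_quadratic_closed_form(self):
        """One target, huge drug excess: free fraction from the exact
        single-site quadratic solution."""
        profile = ProteinProfile("single", bak=0, bax=0, bcl2=100.0,
                                 bclxl=0.0, mcl1=0.0)
        drug = DrugSpec("d", kd_bcl2=0.01, kd_bclxl=1e12, kd_mcl1=1e12,
                        dose=1e4)
        free = equilibrium_free_fractions(profile, drug)
        # exact: free = (-(K + D - X) + sqrt((K + D - X)^2 + 4 K X)) / 2
        K, D, X = 0.01, 1e4, 100.0
        b = K + D - X
        exact = (-b + np.sqrt(b * b + 4 * K * X)) / 2.0
        assert free["bcl2"] == pytest.approx(exact, rel=1e-6)
        assert free["bcl2"] / X == pytest.approx(1.01e-6, rel=1e-2)

    def test_infinitely_weak_drug_binds_nothing(self):
        drug = DrugSpec("weak", 1e12, 1e12, 1e12, dose=1e5)
        free = equilibrium_free_fractions(CRC0076, drug)
        for name, total in (("bcl2", CRC0076.bcl2), ("bclxl", CRC0076.bclxl),
                            ("mcl1", CRC0076.mcl1)):
            assert free[name] == pytest.approx(total, rel=1e-6)

    def test_long_time_ode_limit_matches_equilibrium(self, rng):
        """Binding-only kinetics relax onto the competitive equilibrium."""
        params = KineticParameters(k_act=0.0, k_oligo=0.0, k_deg_bh3=0.0,
                                   k_on=1e-2, horizon=100.0)
        drug_base = DrugSpec("d", kd_bcl2=10.0, kd_bclxl=48.0, kd_mcl1=444.0)
        for i in range(5):
            profile = random_profile(rng, f"eq{i}",
                                     effector_range=(100.0, 500.0),
                                     anti_range=(200.0, 2000.0))
            drug = drug_base.at_dose(float(rng.uniform(100.0, 3000.0)))
            stress = StressInput(float(rng.uniform(0.0, 2000.0)))
            traj = simulate_network(
                build_initial_state(profile, drug, stress), params, drug)
            expected = equilibrium_free_fractions(
                profile, drug, params.kd_matrix, stress=stress)
            for name in ("bcl2", "bclxl", "mcl1"):
                ode_free = traj.states[-1, IDX[name]]
                assert ode_free == pytest.approx(expected[name], rel=1e-3)


def test_trajectory_tidy_export(tmp_path, default_params):
    traj = _simulate(CRC0076, 1000.0, default_params,
                     t_eval=np.linspace(0, 12, 5))
    df = traj.to_tidy_frame()
    assert set(df.columns) == {"time_h", "species", "concentration_nM"}
    assert len(df) == 5 * len(IDX)
    traj.summary_json(tmp_path / "summary.json")
    assert (tmp_path / "summary.json").exists()
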