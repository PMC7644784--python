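"""Batch simulation: conservation laws, mode equivalences, scaling behavior."""

import numpy as np
import pytest

from sxm import (
    KineticParams,
    Scenario,
    SimulationConfig,
    parse_formula,
    profile_batch,
    rate_set,
    scaling_experiment,
    simulate_batch,
    specific_rates,
)
from sxm.stoichiometry import I_HCO3, I_OC


def _total_carbon(traj):
    a = np.array([float(p.formula.c) for p in traj.config.compounds])
    return traj.oc @ a + traj.hco3 + traj.biomass.sum(axis=1)


@pytest.fixture(scope="module")
def three_profiles():
    return profile_batch(
        [parse_formula(t) for t in ("C6H12O6", "C10H16N2O4", "C5H8O4")]
    )


@pytest.fixture(scope="module")
def glucose_run(glucose_profile):
    cfg = SimulationConfig(
        compounds=[glucose_profile],
        oc0=[2.0],
        o2_0=20.0,  # far in excess of the ~6 mol O2 per mol glucose needed
        b0=0.01,
        t_span=(0.0, 6.0),
    )
    return simulate_batch(cfg)


def test_single_compound_stoichiometric_closure(glucose_run, glucose_profile):
    """Bicarbonate produced per carbon consumed must match the metabolic
    stoichiometry along the whole trajectory."""
    traj = glucose_run
    y = glucose_profile.y_met
    d_hco3 = traj.hco3[-1] - traj.hco3[0]
    d_oc_carbon = 6.0 * (traj.oc[0, 0] - traj.oc[-1, 0])
    assert d_oc_carbon > 0.1  # something actually happened
    expected = y[I_HCO3] / (6.0 * abs(y[I_OC]))
    assert d_hco3 / d_oc_carbon == pytest.approx(expected, rel=1e-6)


def test_carbon_conservation_and_monotonicity(glucose_run):
    total = _total_carbon(glucose_run)
    drift = np.max(np.abs(total - total[0])) / total[0]
    assert drift < 1e-6
    assert (np.diff(glucose_run.oc[:, 0]) <= 1e-12).all()
    assert (np.diff(glucose_run.o2) <= 1e-12).all()
    assert (np.diff(glucose_run.hco3) >= -1e-12).all()
    assert (np.diff(glucose_run.biomass[:, 0]) >= -1e-12).all()
    assert glucose_run.oc.min() > -1e-10 and glucose_run.o2.min() > -1e-10


def test_zero_biomass_is_a_fixed_point(glucose_profile):
    cfg = SimulationConfig(
        compounds=[glucose_profile], oc0=[1.0], o2_0=5.0, b0=0.0, t_span=(0, 3)
    )
    traj = simulate_batch(cfg)
    assert np.allclose(traj.oc, 1.0) and np.allclose(traj.o2, 5.0)
    assert np.allclose(traj.biomass, 0.0)


def test_identical_compounds_share_allocation_equally(glucose_profile):
    cfg = SimulationConfig(
        compounds=[glucose_profile, glucose_profile],
        oc0=[1.0, 1.0],
        o2_0=10.0,
        b0=0.01,
        mode="sxm_exm",
        t_span=(0, 3),
    )
    traj = simulate_batch(cfg)
    assert traj.u is not None
    np.testing.assert_allclose(traj.u, 0.5, atol=1e-9)


def test_single_guild_mxm_reproduces_sxm(three_profiles):
    base = dict(
        compounds=three_profiles, oc0=[1.0, 0.5, 0.8], o2_0=10.0, b0=0.01, t_span=(0, 4)
    )
    t_sxm = simulate_batch(SimulationConfig(mode="sxm", **base))
    t_mxm = simulate_batch(SimulationConfig(mode="sxm_mxm", **base))
    np.testing.assert_allclose(t_mxm.oc, t_sxm.oc, atol=1e-9)
    np.testing.assert_allclose(t_mxm.biomass, t_sxm.biomass, atol=1e-9)


def test_regulated_consumption_never_exceeds_unregulated(three_profiles):
    base = dict(
        compounds=three_profiles, oc0=[1.0, 0.5, 0.8], o2_0=10.0, b0=0.01, t_span=(0, 4)
    )
    t_plain = simulate_batch(SimulationConfig(mode="sxm", **base))
    t_reg = simulate_batch(SimulationConfig(mode="sxm_exm", **base))
    # regulation slows total substrate consumption at every time point
    plain_left = t_plain.oc.sum(axis=1)
    reg_left = t_reg.oc.sum(axis=1)
    assert (reg_left >= plain_left - 1e-9).all()
    assert reg_left[-1] > plain_left[-1]


def test_specific_rates_match_rate_set_at_t0(glucose, glucose_profile):
    v_h, oc0, o2_0 = 1.0, 2.0, 20.0
    cfg = SimulationConfig(
        compounds=[glucose_profile], oc0=[oc0], o2_0=o2_0, b0=0.01, v_h=v_h,
        t_span=(0, 1),
    )
    sr = specific_rates(simulate_batch(cfg)).iloc[0]
    rs = rate_set(
        glucose_profile.y_met, glucose, KineticParams(),
        Scenario.both_limited(v_h * oc0, v_h * o2_0),
    )
    assert sr["mu"] == pytest.approx(rs.mu, rel=1e-9)
    assert sr["r_o2"] == pytest.approx(rs.r_o2, rel=1e-9)
    assert sr["r_c"] == pytest.approx(rs.r_c, rel=1e-9)


def test_specific_rates_additivity_and_regulation(glucose_profile):
    """n identical compounds: unregulated specific rate scales n-fold,
    regulated specific rate stays at the single-compound value (at t=0)."""
    n = 3
    single = SimulationConfig(
        compounds=[glucose_profile], oc0=[1.0], o2_0=10.0, b0=0.01, t_span=(0, 1)
    )
    r1 = specific_rates(simulate_batch(single)).iloc[0]["r_o2"]
    for mode, factor in (("sxm", n), ("sxm_exm", 1)):
        cfg = SimulationConfig(
            compounds=[glucose_profile] * n, oc0=[1.0] * n, o2_0=10.0, b0=0.01,
            mode=mode, t_span=(0, 1),
        )
        rn = specific_rates(simulate_batch(cfg)).iloc[0]["r_o2"]
        assert rn == pytest.approx(factor * r1, rel=1e-9)


def test_config_validation(glucose_profile, three_profiles):
    with pytest.raises(ValueError, match="non-negative"):
        SimulationConfig(compounds=[glucose_profile], oc0=[-1.0], o2_0=1.0, b0=0.01)
    with pytest.raises(ValueError, match="one concentration per compound"):
        SimulationConfig(compounds=three_profiles, oc0=[1.0], o2_0=1.0, b0=0.01)
    with pytest.raises(ValueError, match="mode"):
        SimulationConfig(compounds=[glucose_profile], oc0=[1.0], o2_0=1.0, b0=0.01,
                         mode="bogus")
    with pytest.raises(ValueError, match="sxm_mxm"):
        SimulationConfig(compounds=[glucose_profile], oc0=[1.0], o2_0=1.0,
                         b0=[0.01, 0.01], mu_max=[1.0, 2.0])
    import warnings

    from sxm import MolecularFormula, compound_thermo_profile

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bad = compound_thermo_profile(MolecularFormula(c=1, h=0, o=2, label="bad"))
    with pytest.raises(ValueError, match="flagged"):
        SimulationConfig(compounds=[bad], oc0=[1.0], o2_0=1.0, b0=0.01)


def test_trajectory_tidy_export(tmp_path, glucose_run):
    out = tmp_path / "traj.csv"
    glucose_run.write_csv(out)
    import pandas as pd

    df = pd.read_csv(out)
    assert set(df.columns) == {"time", "variable", "value"}
    assert {"O2", "HCO3-"}.issubset(set(df.variable.unique()))


def test_scaling_homogeneous_pool_is_exactly_additive(glucose_profile):
    pool = [glucose_profile] * 60
    table = scaling_experiment(pool, sizes=[10, 50], mode="sxm", seed=1)
    r = table.set_index("n_compounds")["specific_r_o2"]
    assert r[50] / r[10] == pytest.approx(5.0, rel=1e-12)


def test_scaling_validation(glucose_profile):
    with pytest.raises(ValueError, match="two pool sizes"):
        scaling_experiment([glucose_profile] * 5, sizes=[3], mode="sxm")
    with pytest.raises(ValueError, match="smaller"):
        scaling_experiment([glucose_profile] * 5, sizes=[3, 10], mode="sxm")
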