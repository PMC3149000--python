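"""Synthetic-scenario generator: determinism, exact ground truth, physiology."""

import numpy as np
import pytest

from coliflux.rates import detect_overflow_onset, specific_rates_astat
from coliflux.synth import (
    ScenarioConfig,
    ScenarioInfeasibleError,
    forward_simulate,
    generate_scenario,
    true_state,
)


def test_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(overflow_onset_mu=0.5)  # above mu_range top
    with pytest.raises(ValueError):
        ScenarioConfig(wasting_end_frac=1.5)
    with pytest.raises(ValueError):
        ScenarioConfig(regime="batch")


def test_same_seed_reproduces_different_seed_differs():
    cfg = ScenarioConfig(seed=5, mu_range=(0.15, 0.35),
                         overflow_onset_mu=0.25, fast_accumulation_mu=0.33)
    s1, _ = generate_scenario(cfg)
    s2, _ = generate_scenario(cfg)
    assert np.array_equal(s1.biomass, s2.biomass)
    for sp in s1.broth_concentrations:
        assert np.array_equal(s1.broth_concentrations[sp],
                              s2.broth_concentrations[sp])
    s3, _ = generate_scenario(ScenarioConfig(seed=6, mu_range=(0.15, 0.35),
                                             overflow_onset_mu=0.25,
                                             fast_accumulation_mu=0.33))
    assert not np.array_equal(s1.biomass, s3.biomass)


def test_ground_truth_balances_exactly(astat_clean, net):
    _, truth = astat_clean
    for sol in truth.flux_solutions[::10]:
        scale = max(1.0, max(abs(v) for v in sol.fluxes.values()))
        assert max(abs(r) for r in sol.residuals.values()) <= 1e-9 * scale


def test_acetate_profile_is_two_phase(astat_clean):
    _, truth = astat_clean
    mus = truth.mu
    q = np.array([s.q_products.get("acetate", 0.0) for s in truth.snapshots])
    assert np.all(q[mus < 0.27] == 0.0)
    assert np.all(q[mus > 0.29] > 0.0)
    # second phase accelerates: mean slope beyond 0.46 far exceeds the
    # linear first-phase slope
    slope1 = np.gradient(q, mus)[(mus > 0.30) & (mus < 0.44)].mean()
    slope2 = np.gradient(q, mus)[(mus > 0.465) & (mus <= 0.48)].mean()
    assert slope2 > 3 * slope1


def test_pyrimidine_three_phase_pattern(astat_clean):
    """Per-biomass DHO rises to the overflow onset then declines; CBASP and
    orotate rise again in the fast-accumulation phase."""
    _, truth = astat_clean
    mus = truth.mu

    def per_biomass(sp):
        return np.array([s.q_products[sp] / s.mu for s in truth.snapshots])

    dho = per_biomass("DHO")
    i_onset = np.argmin(np.abs(mus - 0.27))
    assert dho[i_onset] > dho[0]
    assert dho[-1] < dho[i_onset]
    for sp in ("CBASP", "orotate"):
        prod = per_biomass(sp)
        i_fast = np.argmin(np.abs(mus - 0.46))
        assert prod[-1] > prod[i_fast]


def test_onset_parameter_read_back(astat_clean):
    _, truth = astat_clean
    onset = detect_overflow_onset(truth.snapshots[::4])
    assert onset == pytest.approx(0.27, rel=0.02)


def test_forward_simulate_zero_and_imbalanced():
    from coliflux.solver import FluxSolution

    zero = FluxSolution(
        fluxes={rid: 0.0 for rid in ["Pts", "Co2Out", "AceOut", "Vprod"]},
        fixed_mask={}, residuals={"PYR": 0.0}, condition_diagnostic=1.0,
    )
    snap = forward_simulate(zero, 0.0, 1.0)
    assert snap.q_glc == 0.0 and snap.r_co2 == 0.0
    bad = FluxSolution(
        fluxes={"Pts": 1.0}, fixed_mask={}, residuals={"PYR": 1.0},
        condition_diagnostic=1.0,
    )
    with pytest.raises(ValueError, match="imbalanced"):
        forward_simulate(bad, 0.1, 1.0)


def test_boundary_carbon_identity(net, comp_table):
    """Carbon crossing the boundary in the snapshot equals the flux
    vector's boundary carbon."""
    snap, truth, _ = true_state(ScenarioConfig(noise_cv=0), 0.42, net, comp_table)
    full = forward_simulate(truth, 0.42, 2.0, net)
    from coliflux.network import carbon_count

    snap_out = full.r_co2 + sum(
        q * carbon_count(sp, net) for sp, q in full.q_products.items() if q > 0
    )
    drain_carbon = sum(
        float(net.drain_carbon_capture(r.id)) * truth.fluxes[r.id]
        for r in net.reactions_by_role("biomass_drain")
    )
    assert 6 * full.q_glc == pytest.approx(snap_out + drain_carbon, rel=1e-9)


def test_infeasible_profile_raises(net, comp_table):
    cfg = ScenarioConfig(noise_cv=0.0, biomass_yield=0.75)  # beyond physical
    with pytest.raises(ScenarioInfeasibleError):
        true_state(cfg, 0.3, net, comp_table)


def test_dstat_uptake_scales_with_capability(net, comp_table):
    q = []
    for c in (0.2, 0.5, 0.8):
        cfg = ScenarioConfig(regime="dstat", dilution_rate=0.3,
                             coutilisation_capability=c, noise_cv=0.0)
        snap, _, _ = true_state(cfg, 0.3, net, comp_table)
        q.append(snap.q_products["acetate"])
    assert q[0] > q[1] > q[2]  # more capability, more negative (uptake)
    assert all(v < 0 for v in q)


def test_generated_series_consistent_with_rates_module():
    cfg = ScenarioConfig(regime="chemostat", dilution_rate=0.2, noise_cv=0.0,
                         duration_h=12.0, seed=2)
    series, truth = generate_scenario(cfg)
    from coliflux.rates import specific_rates_chemostat

    snap = specific_rates_chemostat(series, (6.0, 12.0))
    true = truth.snapshots[-1]
    assert snap.q_glc == pytest.approx(true.q_glc, rel=1e-9)
    assert snap.r_co2 == pytest.approx(true.r_co2, rel=1e-9)
    for sp, v in true.q_products.items():
        if sp == "Vprod":
            continue
        assert snap.q_products[sp] == pytest.approx(v, rel=1e-6, abs=1e-12)
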