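"""Independent brute-force reference solver for oracle-equivalence tests.

Stacks all 22 balance rows, one row per fixed flux and the regime
constraints into a single dense system over all 50 fluxes and solves it by
least squares — no variable elimination, no staging, no reuse of the package
solver's code path.
"""

from __future__ import annotations

import numpy as np

from coliflux.network import SPECIES_TO_OUTFLOW, stoichiometric_matrix


def brute_force_solve(network, snapshot, drains, regime):
    S = stoichiometric_matrix(network, float_dtype=True)
    rids = [r.id for r in network.reactions]
    col = {rid: j for j, rid in enumerate(rids)}
    rows = [S]
    rhs = [np.zeros(S.shape[0])]

    def fix(rid, value):
        e = np.zeros((1, len(rids)))
        e[0, col[rid]] = 1.0
        rows.append(e)
        rhs.append(np.array([value]))

    fix("Pts", snapshot.q_glc)
    for sp, rid in SPECIES_TO_OUTFLOW.items():
        if sp == "CO2":
            fix(rid, snapshot.r_co2)
        else:
            fix(rid, snapshot.q_products.get(sp, 0.0))
    for r in network.reactions_by_role("biomass_drain"):
        fix(r.id, drains.get(r.id, 0.0))
    if regime == "net_excretion":
        fix("Acs", 0.0)
        fix("AceAB", 0.0)
    else:
        fix("Pta", 0.0)
        tie = np.zeros((1, len(rids)))
        tie[0, col["AceAB"]] = 1.0
        tie[0, col["Acs"]] = -network.glyoxylate_coupling
        rows.append(tie)
        rhs.append(np.zeros(1))
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    v, *_ = np.linalg.lstsq(A, b, rcond=None)
    return {rid: float(v[col[rid]]) for rid in rids}


def random_feasible_snapshot(rng, network, comp_table):
    """Random physiological snapshot plus matched drains (for solver
    cross-checks; signs of dependent fluxes are not constrained)."""
    from coliflux.biomass import composition_at_mu, drain_fluxes
    from coliflux.rates import SteadyStateSnapshot

    mu = rng.uniform(0.1, 0.48)
    q_glc = mu / (rng.uniform(0.40, 0.52) * 0.18016)
    products = {
        "acetate": rng.uniform(-0.5, 1.0),
        "lactate": rng.uniform(0, 0.1),
        "CBASP": rng.uniform(0, 0.2),
        "DHO": rng.uniform(0, 0.1),
        "orotate": rng.uniform(0, 0.15),
        "NAA": rng.uniform(0, 0.1),
    }
    r_co2 = rng.uniform(0.3, 0.5) * 6 * q_glc
    snap = SteadyStateSnapshot(mu, q_glc, products, r_co2)
    comp = composition_at_mu(comp_table, mu)
    drains = drain_fluxes(comp, mu, network)
    return snap, drains
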