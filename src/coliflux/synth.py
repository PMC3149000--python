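"""Synthetic A-stat / D-stat / chemostat scenarios with known ground truth.

The generator emulates the qualitative physiology of glucose-limited
E. coli K-12 continuous cultures:

* two-phase acetate overflow starting at mu = 0.27 1/h with faster
  accumulation beyond mu = 0.46 1/h;
* three-phase excretion of the pyrimidine-pathway intermediates
  (carbamoyl-aspartate and dihydroorotate rise until overflow onset, then
  DHO declines while CBASP and orotate plateau and rise again in the fast
  phase), plus steadily increasing N-acetyl-aspartate and lactate;
* total carbon wasting to non-CO2 by-products rising from 3 % to 11 % of
  consumed carbon over the mu ramp at constant biomass yield;
* D-stat glucose-acetate co-utilisation with an uptake capability that the
  caller sets per dilution rate, and a wasting plateau (default 5.5 %).

Profiles are piecewise-smooth parametric curves anchored at the named mu
breakpoints, not mechanistic kinetics.  For every time point the generator
builds an exactly balanced flux vector by fixing the exchange fluxes implied
by the profiles (with the excess-carbon outflow Vprod = 0 and the CO2 outflow
left free) and solving the network; measured concentration series are then
emitted through the inverse of the quasi-steady-state rate balances, with
multiplicative log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .biomass import (
    CompositionTable,
    composition_at_mu,
    default_composition_table,
    drain_fluxes,
)
from .network import (
    MetabolicNetwork,
    SPECIES_TO_OUTFLOW,
    OUTFLOW_TO_SPECIES,
    build_default_network,
)
from .rates import GLUCOSE_MOLAR_MASS, CultureTimeSeries, SteadyStateSnapshot
from .solver import (
    NET_ASSIMILATION,
    NET_EXCRETION,
    FluxSolution,
    RESIDUAL_TOL,
    solve_determined_system,
)

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "ScenarioInfeasibleError",
    "generate_scenario",
    "forward_simulate",
    "true_state",
]

WASTED_SPECIES = ("acetate", "lactate", "CBASP", "DHO", "orotate", "NAA")


class ScenarioInfeasibleError(ValueError):
    """No physically sensible balanced flux vector exists for the profile."""


@dataclass
class ScenarioConfig:
    regime: str = "astat"                   # astat | dstat | chemostat
    acceleration: float = 0.01              # 1/h^2 (A-stat)
    mu_range: tuple[float, float] = (0.10, 0.48)
    overflow_onset_mu: float = 0.27
    fast_accumulation_mu: float = 0.46
    pdh_saturation_mu: float = 0.42
    wasting_start_frac: float = 0.03
    wasting_end_frac: float = 0.11
    dstat_wasting_plateau: float = 0.055
    coutilisation_capability: float = 0.5   # D-stat only, in [0, 1]
    noise_cv: float = 0.02
    seed: int = 0
    # cultivation constants
    dilution_rate: float = 0.30             # 1/h (dstat / chemostat)
    duration_h: float = 24.0                # dstat / chemostat length
    biomass_yield: float = 0.46             # g DCW per g glucose
    feed_glucose: float = 25.0              # mM (~4.5 g/L)
    feed_acetate: float = 30.0              # mM (dstat co-feed)
    residual_glucose: float = 0.05          # mM
    acetate_uptake_max: float = 2.0         # mmol/gDCW/h at capability 1
    acetate_second_phase_shape: float = 2.0 # steepness of the fast phase
    #: unmeasured excess carbon (ground-truth Vprod) as a fraction of carbon
    #: in at mu_max; the measured carbon balance is unclosed by this much at
    #: high mu, rising linearly from zero at the overflow onset
    unclosed_gap_end_frac: float = 0.05
    #: the A-stat ramp continues this far beyond mu_range[1] (with the
    #: wasting fractions held at their ramp-top values), so that rates at
    #: mu_range[1] itself can be estimated from interior data
    mu_margin: float = 0.03
    sample_interval_h: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.mu_range
        if not (lo < self.overflow_onset_mu < self.fast_accumulation_mu < hi):
            raise ValueError(
                "require mu_min < overflow_onset_mu < fast_accumulation_mu < mu_max"
            )
        for name in ("wasting_start_frac", "wasting_end_frac",
                     "dstat_wasting_plateau", "coutilisation_capability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.regime not in ("astat", "dstat", "chemostat"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class GroundTruth:
    """Per-time-point true snapshots and flux solutions."""

    config: ScenarioConfig
    time: np.ndarray
    mu: np.ndarray
    snapshots: list[SteadyStateSnapshot]
    flux_solutions: list[FluxSolution]
    biomass: np.ndarray


_MINOR_SPECIES = ("CBASP", "DHO", "lactate", "NAA", "orotate")


def _byproduct_reference() -> "pd.DataFrame":
    """Measured per-biomass by-product levels (mmol/gDCW) vs mu, used as
    anchors for the minor-species excretion profiles."""
    global _BYPRODUCT_REF
    if _BYPRODUCT_REF is None:
        from importlib.resources import files
        import io as _io
        import pandas as pd

        text = files("coliflux").joinpath("data/byproduct_reference.csv").read_text()
        _BYPRODUCT_REF = pd.read_csv(_io.StringIO(text), comment="#")
    return _BYPRODUCT_REF


_BYPRODUCT_REF = None


def minor_byproduct_levels(mu: float) -> dict[str, float]:
    """Per-biomass levels O_s (mmol/gDCW) of the five minor by-products at
    mu: linear interpolation through the measured A-stat anchors, linear
    extrapolation from the outermost segments, clipped at zero.  The
    specific excretion rate is q_s = O_s * mu."""
    ref = _byproduct_reference()
    out = {}
    for sp in _MINOR_SPECIES:
        sub = ref[ref.species == sp]
        mus = sub.mu.to_numpy(dtype=float)
        vals = sub.astat_mean.fillna(0.0).to_numpy(dtype=float)
        if mu <= mus[0]:
            slope = (vals[1] - vals[0]) / (mus[1] - mus[0])
            o = vals[0] + slope * (mu - mus[0])
        elif mu >= mus[-1]:
            slope = (vals[-1] - vals[-2]) / (mus[-1] - mus[-2])
            o = vals[-1] + slope * (mu - mus[-1])
        else:
            o = float(np.interp(mu, mus, vals))
        out[sp] = max(o, 0.0)
    return out


def _minor_carbon_fraction(
    mu: float, carbon_in_per_mu: float, carbons: dict[str, int]
) -> float:
    levels = minor_byproduct_levels(mu)
    return sum(levels[sp] * carbons[sp] for sp in levels) / carbon_in_per_mu


def wasting_split(
    config: ScenarioConfig,
    mu: float,
    carbons: dict[str, int] | None = None,
) -> dict[str, float]:
    """Per-species carbon-wasting fractions at mu for the A-stat profile.

    Minor species follow the measured per-biomass anchors, scaled globally so
    their summed carbon fraction equals ``wasting_start_frac`` at mu_min
    (below the overflow onset all wasting is in the minor species).  Acetate
    is zero below the onset, then rises with a linear first phase and a steep
    second phase beyond ``fast_accumulation_mu``; its amplitude is set so
    total wasting reaches ``wasting_end_frac`` at mu_max.
    """
    carbons = carbons or {"acetate": 2, "lactate": 3, "CBASP": 5, "DHO": 5,
                          "orotate": 5, "NAA": 6}
    lo, hi = config.mu_range
    onset = config.overflow_onset_mu
    fast = config.fast_accumulation_mu
    # carbon in per unit mu (q_glc = mu / (Y * M_glc))
    cin_per_mu = 6.0 / (config.biomass_yield * GLUCOSE_MOLAR_MASS)
    scale = config.wasting_start_frac / _minor_carbon_fraction(
        lo, cin_per_mu, carbons
    )
    levels = minor_byproduct_levels(mu)
    split = {
        sp: scale * levels[sp] * carbons[sp] / cin_per_mu for sp in levels
    }
    minors_at_hi = scale * _minor_carbon_fraction(hi, cin_per_mu, carbons)
    amplitude = config.wasting_end_frac - minors_at_hi
    if amplitude <= 0:
        raise ScenarioInfeasibleError(
            "wasting_end_frac leaves no room for acetate above the minor "
            "by-products; increase it or lower wasting_start_frac"
        )
    s = 2.0 * config.acetate_second_phase_shape / max(hi - fast, 1e-9)

    def shape(m: float) -> float:
        linear = 0.7 * max(m - onset, 0.0) / (hi - onset)
        second = 0.3 * np.expm1(s * max(m - fast, 0.0)) / np.expm1(s * (hi - fast))
        return linear + float(second)

    split["acetate"] = amplitude * shape(mu)
    return split


def _carbon_counts(network: MetabolicNetwork) -> dict[str, int]:
    counts = {}
    for species, rid in SPECIES_TO_OUTFLOW.items():
        rxn = network.reaction(rid)
        consumed = [m for m, c in rxn.stoichiometry.items() if c < 0]
        carbons = max(
            network.metabolite(m).carbon_atoms for m in consumed
        )
        counts[species] = carbons
    return counts


def true_state(
    config: ScenarioConfig,
    mu: float,
    network: MetabolicNetwork,
    comp_table: CompositionTable,
    coutilisation: float | None = None,
) -> tuple[SteadyStateSnapshot, FluxSolution, dict[str, float]]:
    """Exactly balanced physiological state at one mu.

    Returns (snapshot, flux solution, drain fluxes).  The CO2 rate is the
    one implied by the network balances (CO2 outflow solved, Vprod = 0).
    """
    comp = composition_at_mu(comp_table, mu)
    drains = drain_fluxes(comp, mu, network)
    q_glc = mu / (config.biomass_yield * GLUCOSE_MOLAR_MASS)

    if config.regime == "dstat":
        c = config.coutilisation_capability if coutilisation is None else coutilisation
        D = config.dilution_rate
        X = config.biomass_yield * GLUCOSE_MOLAR_MASS * (
            config.feed_glucose - config.residual_glucose
        )
        avail = 0.9 * D * config.feed_acetate / X
        q_ace = -min(c * config.acetate_uptake_max, avail)
    else:
        q_ace = None  # from the wasting split

    carbons = _carbon_counts(network)
    carbon_in = 6.0 * q_glc + (2.0 * -q_ace if q_ace is not None and q_ace < 0 else 0.0)

    # beyond the analysis range the by-product fractions hold their
    # ramp-top values (the exponential acetate phase does not continue)
    mu_profile = min(mu, config.mu_range[1])
    split = wasting_split(config, mu_profile, carbons)
    if config.regime == "dstat":
        # acetate is co-consumed; the five minor species sum to the plateau
        minor = {k: v for k, v in split.items() if k != "acetate"}
        scale = config.dstat_wasting_plateau / sum(minor.values())
        split = {k: scale * v for k, v in minor.items()}

    q_products = {
        sp: split[sp] * carbon_in / carbons[sp] for sp in split
    }
    if q_ace is not None:
        q_products["acetate"] = q_ace

    # unmeasured excess carbon (Vprod): the measured balance is unclosed by
    # a fraction rising from 0 at the overflow onset to unclosed_gap_end_frac
    lo, hi = config.mu_range
    onset = config.overflow_onset_mu
    gap_frac = config.unclosed_gap_end_frac * float(
        np.clip((mu - onset) / max(hi - onset, 1e-9), 0.0, 1.0)
    )
    v_vprod = gap_frac * carbon_in / 4.0

    fixed: dict[str, float] = {"Pts": q_glc, "Vprod": v_vprod}
    for sp, q in q_products.items():
        fixed[SPECIES_TO_OUTFLOW[sp]] = q
    for rid, v in drains.items():
        fixed[rid] = v

    gamma = network.glyoxylate_coupling
    if q_products.get("acetate", 0.0) > 0:
        fixed["Acs"] = 0.0
        fixed["AceAB"] = 0.0
        ties = []
    else:
        fixed["Pta"] = 0.0
        ties = [({"AceAB": 1.0, "Acs": -gamma}, 0.0)]

    sol = solve_determined_system(network, fixed, ties)
    worst = max(abs(r) for r in sol.residuals.values())
    if worst > RESIDUAL_TOL:
        raise ScenarioInfeasibleError(
            f"no balanced flux vector at mu={mu:.3f} (residual {worst:.2e})"
        )
    essential = ("AtpD", "Oxp", "Zwf", "Pdh", "GltA", "Icd", "SucAB")
    bad = [rid for rid in essential if sol.fluxes[rid] < -1e-9]
    if bad:
        raise ScenarioInfeasibleError(
            f"profile at mu={mu:.3f} requires negative fluxes in {bad}; "
            "adjust yield/wasting/composition parameters"
        )
    r_co2 = sol.fluxes["Co2Out"]
    snap = SteadyStateSnapshot(
        mu=mu,
        q_glc=q_glc,
        q_products=q_products,
        r_co2=r_co2,
        biomass_yield=config.biomass_yield,
    )
    sol.regime = NET_EXCRETION if q_products.get("acetate", 0.0) > 0 else NET_ASSIMILATION
    return snap, sol, drains


def forward_simulate(
    flux: FluxSolution,
    mu: float,
    X: float,
    network: MetabolicNetwork | None = None,
) -> SteadyStateSnapshot:
    """Measured exchange rates implied by a balanced flux vector."""
    net = network or build_default_network()
    worst = max(abs(r) for r in flux.residuals.values()) if flux.residuals else 0.0
    scale = max(1.0, max(abs(v) for v in flux.fluxes.values()))
    if worst > RESIDUAL_TOL * scale:
        raise ValueError(
            f"imbalanced flux input (worst residual {worst:.2e})"
        )
    q_glc = flux.fluxes["Pts"]
    q_products = {}
    r_co2 = 0.0
    for rid, sp in OUTFLOW_TO_SPECIES.items():
        if rid not in flux.fluxes:
            continue
        if sp == "CO2":
            r_co2 = flux.fluxes[rid]
        else:
            q_products[sp] = flux.fluxes[rid]
    # the excess-carbon outflow is a boundary flux of the vector; reporting it
    # as a pseudo-species keeps boundary carbon of snapshot and vector equal
    if abs(flux.fluxes.get("Vprod", 0.0)) > 0:
        q_products["Vprod"] = flux.fluxes["Vprod"]
    yield_xs = mu / (q_glc * GLUCOSE_MOLAR_MASS) if q_glc > 0 else float("nan")
    return SteadyStateSnapshot(mu, q_glc, q_products, r_co2, yield_xs)


# ---------------------------------------------------------------------------
# scenario generation
# ---------------------------------------------------------------------------

def _mu_schedule(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(time, D, mu_true) for the configured regime."""
    if config.regime == "astat":
        lo, hi = config.mu_range
        t_end = (hi + config.mu_margin - lo) / config.acceleration
        t = np.arange(0.0, t_end + 1e-9, config.sample_interval_h)
        D = lo + config.acceleration * t
    else:
        t = np.arange(0.0, config.duration_h + 1e-9, config.sample_interval_h)
        D = np.full_like(t, config.dilution_rate)
    return t, D, D.copy()  # quasi steady state: mu = D


def generate_scenario(
    config: ScenarioConfig,
    network: MetabolicNetwork | None = None,
    comp_table: CompositionTable | None = None,
) -> tuple[CultureTimeSeries, GroundTruth]:
    """Generate a cultivation time series plus its exact ground truth.

    Same seed gives identical output; ``noise_cv = 0`` gives noise-free data
    from which the pipeline recovers the true fluxes to numerical precision.
    """
    net = network or build_default_network()
    table = comp_table or default_composition_table()
    rng = np.random.default_rng(config.seed)

    t, D, mu = _mu_schedule(config)
    n = len(t)
    X = np.empty(n)
    snapshots: list[SteadyStateSnapshot] = []
    fluxes: list[FluxSolution] = []
    X_const = config.biomass_yield * GLUCOSE_MOLAR_MASS * (
        config.feed_glucose - config.residual_glucose
    )
    for k in range(n):
        snap, sol, _ = true_state(config, float(mu[k]), net, table)
        snapshots.append(snap)
        fluxes.append(sol)
        X[k] = X_const

    species = [sp for sp in WASTED_SPECIES]
    q = {sp: np.array([s.q_products.get(sp, 0.0) for s in snapshots])
         for sp in species}

    feed = {
        "glucose": np.full(n, config.feed_glucose),
        "acetate": np.full(
            n, config.feed_acetate if config.regime == "dstat" else 0.0
        ),
    }

    # broth concentrations by integrating dP/dt = q_P X - D (P - P_feed)
    broth: dict[str, np.ndarray] = {
        "glucose": np.full(n, config.residual_glucose)
    }
    for sp in species:
        qs = q[sp]

        def rhs(tt, P, qs=qs, sp=sp):
            qq = np.interp(tt, t, qs)
            DD = np.interp(tt, t, D)
            return qq * X_const - DD * (P - feed.get(sp, np.zeros(n))[0])

        P0 = feed.get(sp, np.zeros(1))[0] + q[sp][0] * X_const / D[0]
        res = solve_ivp(
            rhs, (t[0], t[-1]), [max(P0, 0.0)], t_eval=t,
            rtol=1e-10, atol=1e-12, method="LSODA",
        )
        if not res.success:
            raise RuntimeError(f"concentration integration failed for {sp}")
        broth[sp] = res.y[0]

    cer = np.array([s.r_co2 for s in snapshots]) * X

    def noisy(arr: np.ndarray) -> np.ndarray:
        if config.noise_cv <= 0:
            return arr.copy()
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=arr.shape)
        return arr * factors

    series = CultureTimeSeries(
        time=t,
        dilution_rate=D,
        biomass=noisy(X),
        feed_concentrations=feed,
        broth_concentrations={k: noisy(v) for k, v in broth.items()},
        co2_rate=noisy(cer),
    )
    truth = GroundTruth(
        config=config, time=t, mu=mu, snapshots=snapshots,
        flux_solutions=fluxes, biomass=X,
    )
    return series, truth
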