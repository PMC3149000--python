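"""Carbon-balance closure per snapshot and wasting profiles across a ramp.

Carbon in (glucose, plus co-fed acetate when it is net-consumed) is
partitioned into biomass, CO2 and each excreted by-product; whatever is not
recovered is reported as the gap, never redistributed.  All fractions are
relative to carbon in, so recoveries plus gap sum to one identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import MetabolicNetwork, build_default_network, carbon_count
from .rates import SteadyStateSnapshot

__all__ = ["CarbonBalance", "carbon_balance", "wasting_profile", "WASTING_SPECIES"]

#: non-CO2 by-products counted as carbon wasting
WASTING_SPECIES = ("acetate", "lactate", "CBASP", "DHO", "orotate", "NAA")


@dataclass
class CarbonBalance:
    """Fractional carbon recovery at one snapshot (all vs carbon in)."""

    mu: float
    frac_biomass: float
    frac_co2: float
    frac_products: dict[str, float]
    gap: float

    @property
    def total_wasting(self) -> float:
        """Summed recovery into the measured non-CO2 by-products."""
        return sum(
            v for k, v in self.frac_products.items() if k in WASTING_SPECIES
        )

    def check_closure(self) -> float:
        """frac_biomass + frac_co2 + sum(products) + gap - 1 (identically 0)."""
        return (
            self.frac_biomass
            + self.frac_co2
            + sum(self.frac_products.values())
            + self.gap
            - 1.0
        )


def carbon_balance(
    snapshot: SteadyStateSnapshot,
    biomass_carbon: float,
    network: MetabolicNetwork | None = None,
) -> CarbonBalance:
    """Carbon balance of one snapshot.

    Parameters
    ----------
    snapshot:
        specific rates; consumed species (negative rates) enter the
        denominator as carbon in, never as negative recovery.
    biomass_carbon:
        mmol carbon per g DCW (from :func:`coliflux.biomass.biomass_carbon`).
    """
    if snapshot.q_glc <= 0:
        raise ValueError("carbon balance requires glucose uptake > 0")
    net = network or build_default_network()
    carbon_in = 6.0 * snapshot.q_glc
    for sp, q in snapshot.q_products.items():
        if q < 0:
            carbon_in += -q * carbon_count(sp, net)
    frac_products = {
        sp: q * carbon_count(sp, net) / carbon_in
        for sp, q in snapshot.q_products.items()
        if q > 0
    }
    frac_biomass = snapshot.mu * biomass_carbon / carbon_in
    frac_co2 = snapshot.r_co2 / carbon_in
    gap = 1.0 - frac_biomass - frac_co2 - sum(frac_products.values())
    return CarbonBalance(
        mu=snapshot.mu,
        frac_biomass=frac_biomass,
        frac_co2=frac_co2,
        frac_products=frac_products,
        gap=gap,
    )


def wasting_profile(balances: list[CarbonBalance]) -> pd.DataFrame:
    """Long-format table of per-species wasting fractions against mu.

    Columns: mu, species, fraction; the pseudo-species ``total`` holds the
    summed wasting at each mu.
    """
    if len(balances) < 2:
        raise ValueError("need at least two balances for a profile")
    rows = []
    for b in sorted(balances, key=lambda b: b.mu):
        for sp in WASTING_SPECIES:
            rows.append(
                {"mu": b.mu, "species": sp,
                 "fraction": b.frac_products.get(sp, 0.0)}
            )
        rows.append({"mu": b.mu, "species": "total", "fraction": b.total_wasting})
    return pd.DataFrame(rows)
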