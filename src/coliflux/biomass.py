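"""Growth-rate dependent biomass composition and biosynthetic drain fluxes.

The composition of E. coli biomass shifts with the specific growth rate mu:
the RNA fraction rises with mu (ribosome demand) and levels off near
mu = 0.40 1/h, while the protein fraction falls correspondingly.  A
``CompositionTable`` stores macromolecular mass fractions and the derived
monomer demands (mmol per g DCW) for each of the network's 18 biomass-drain
reactions; ``drain_fluxes`` converts a composition into drain fluxes at a
given mu (flux = demand * mu, in mmol / g DCW / h).

The default table shipped here is a surrogate assembled from
literature-typical E. coli K-12 values (Neidhardt-style composition, observed
growth Y_ATP for the total growth-associated ATP requirement); it is not a
measured dataset and can be replaced by a user file with the same columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, COFACTORS

__all__ = [
    "BiomassComposition",
    "CompositionTable",
    "composition_at_mu",
    "drain_fluxes",
    "biomass_carbon",
    "default_composition_table",
    "demands_from_macromolecules",
    "read_composition_table",
    "write_composition_table",
    "MACROMOLECULES",
    "DRAIN_IDS",
]

log = logging.getLogger(__name__)

MACROMOLECULES = (
    "protein", "RNA", "DNA", "lipid", "LPS", "murein", "glycogen", "other",
)

DRAIN_IDS = (
    "BmAla", "BmVli", "BmSer", "BmAsp", "BmGlu", "BmAro", "BmHis",
    "BmRnaPur", "BmRnaPyr", "BmDnaPur", "BmDnaPyr",
    "BmAcyl", "BmGlyc3P", "BmLps", "BmMurein", "BmGlycogen", "BmC1",
    "BmAssembly",
)

# average monomer masses (g/mmol) used to convert mass fractions to demands
_M_RESIDUE = 0.110   # amino-acid residue
_M_RNA_NT = 0.324    # ribonucleotide monophosphate
_M_DNA_NT = 0.309    # deoxyribonucleotide monophosphate
_M_PHOSPHOLIPID = 0.750
_M_LPS_SUGAR = 0.200
_M_MUREIN_UNIT = 0.250
_M_GLUCOSE_UNIT = 0.162
_M_C1_POOL = 0.120

# amino-acid family shares of protein residues (mol fraction)
_AA_SHARES = {
    "BmAla": 0.10, "BmVli": 0.21, "BmSer": 0.15, "BmAsp": 0.21,
    "BmGlu": 0.22, "BmAro": 0.08, "BmHis": 0.03,
}
_PURINE_FRACTION_RNA = 0.52
_PURINE_FRACTION_DNA = 0.50

#: growth-associated ATP beyond monomer synthesis (transport, polymerization
#: not in the per-monomer coefficients, turnover, assembly), mmol/gDCW.
#: Sets the total growth-associated ATP demand to ~95 mmol/gDCW, i.e. an
#: observed aerobic growth Y_ATP of ~10.5 g/mol rather than the theoretical
#: Stouthamer minimum.
ASSEMBLY_ATP_DEMAND = 65.0


@dataclass
class BiomassComposition:
    """Composition at one specific growth rate.

    monomer_demands maps biomass-drain reaction ids to mmol monomer per
    g DCW; cofactor_demands is a derived view (net growth-associated
    consumption per g DCW, computed from drain stoichiometry).
    """

    mu: float
    macromolecules: dict[str, float]
    monomer_demands: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.macromolecules.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError(
                f"macromolecule mass fractions sum to {total:.4f}, not 1 +/- 0.01"
            )
        if any(v < 0 for v in self.macromolecules.values()):
            raise ValueError("negative macromolecule fraction")
        if any(v < 0 for v in self.monomer_demands.values()):
            raise ValueError("negative monomer demand")

    def cofactor_demands(self, network: MetabolicNetwork) -> dict[str, float]:
        """Net growth-associated cofactor consumption (mmol per g DCW)."""
        out = {c: 0.0 for c in COFACTORS}
        for rid, demand in self.monomer_demands.items():
            rxn = network.reaction(rid)
            for cof in COFACTORS:
                out[cof] -= demand * float(rxn.stoichiometry.get(cof, 0))
        return out


@dataclass
class CompositionTable:
    entries: list[BiomassComposition]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty composition table")
        mus = [e.mu for e in self.entries]
        if any(b <= a for a, b in zip(mus, mus[1:])):
            raise ValueError("composition-table mu values must strictly increase")

    @property
    def mu_values(self) -> np.ndarray:
        return np.array([e.mu for e in self.entries])


def composition_at_mu(table: CompositionTable, mu: float) -> BiomassComposition:
    """Piecewise-linear interpolation of composition in mu.

    Outside the tabulated range the nearest entry is used (constant
    extrapolation) and a warning is logged.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    entries = table.entries
    mus = table.mu_values
    if mu <= mus[0] or mu >= mus[-1]:
        if len(entries) > 1 and (mu < mus[0] or mu > mus[-1]):
            log.warning(
                "mu=%.3f outside composition table range [%.3f, %.3f]; "
                "using nearest entry", mu, mus[0], mus[-1],
            )
        nearest = entries[0] if mu <= mus[0] else entries[-1]
        return BiomassComposition(
            mu=mu,
            macromolecules=dict(nearest.macromolecules),
            monomer_demands=dict(nearest.monomer_demands),
        )
    hi = int(np.searchsorted(mus, mu))
    lo = hi - 1
    a, b = entries[lo], entries[hi]
    w = (mu - mus[lo]) / (mus[hi] - mus[lo])

    def lerp(da: dict[str, float], db: dict[str, float]) -> dict[str, float]:
        keys = set(da) | set(db)
        return {k: (1 - w) * da.get(k, 0.0) + w * db.get(k, 0.0) for k in keys}

    return BiomassComposition(
        mu=mu,
        macromolecules=lerp(a.macromolecules, b.macromolecules),
        monomer_demands=lerp(a.monomer_demands, b.monomer_demands),
    )


def drain_fluxes(
    comp: BiomassComposition, mu: float, network: MetabolicNetwork
) -> dict[str, float]:
    """Biosynthetic drain fluxes (mmol / g DCW / h): demand * mu per drain."""
    drain_ids = {r.id for r in network.reactions_by_role("biomass_drain")}
    unknown = set(comp.monomer_demands) - drain_ids
    if unknown:
        raise KeyError(
            f"composition references drains absent from the network: {sorted(unknown)}"
        )
    return {rid: comp.monomer_demands.get(rid, 0.0) * mu for rid in sorted(drain_ids)}


def biomass_carbon(comp: BiomassComposition, network: MetabolicNetwork) -> float:
    """Carbon incorporated into biomass, mmol C per g DCW."""
    total = 0.0
    for rid, demand in comp.monomer_demands.items():
        total += demand * float(network.drain_carbon_capture(rid))
    return total


def demands_from_macromolecules(
    macromolecules: dict[str, float],
    assembly_atp: float = ASSEMBLY_ATP_DEMAND,
) -> dict[str, float]:
    """Convert macromolecular mass fractions into per-drain monomer demands."""
    m = macromolecules
    residues = m["protein"] / _M_RESIDUE
    rna_nt = m["RNA"] / _M_RNA_NT
    dna_nt = m["DNA"] / _M_DNA_NT
    phospholipid = m["lipid"] / _M_PHOSPHOLIPID
    demands = {rid: residues * share for rid, share in _AA_SHARES.items()}
    demands.update(
        {
            "BmRnaPur": rna_nt * _PURINE_FRACTION_RNA,
            "BmRnaPyr": rna_nt * (1 - _PURINE_FRACTION_RNA),
            "BmDnaPur": dna_nt * _PURINE_FRACTION_DNA,
            "BmDnaPyr": dna_nt * (1 - _PURINE_FRACTION_DNA),
            "BmAcyl": 2.0 * phospholipid,
            "BmGlyc3P": phospholipid,
            "BmLps": m["LPS"] / _M_LPS_SUGAR,
            "BmMurein": m["murein"] / _M_MUREIN_UNIT,
            "BmGlycogen": m["glycogen"] / _M_GLUCOSE_UNIT,
            "BmC1": m["other"] / _M_C1_POOL,
            "BmAssembly": assembly_atp,
        }
    )
    return demands


# surrogate mu-dependent macromolecule fractions: RNA rises with mu and
# levels off near mu = 0.40 1/h, protein falls correspondingly
_DEFAULT_MACROS = {
    # mu:   protein, RNA,   DNA,   lipid, LPS,   murein, glycogen
    0.10: (0.610, 0.140, 0.031, 0.093, 0.034, 0.025, 0.025),
    0.20: (0.585, 0.165, 0.031, 0.093, 0.034, 0.025, 0.025),
    0.30: (0.560, 0.185, 0.031, 0.093, 0.034, 0.025, 0.025),
    0.40: (0.535, 0.205, 0.031, 0.093, 0.034, 0.025, 0.025),
    0.48: (0.520, 0.208, 0.031, 0.093, 0.034, 0.025, 0.025),
}


def default_composition_table() -> CompositionTable:
    """Surrogate mu-dependent composition table (see module docstring)."""
    entries = []
    for mu, vals in sorted(_DEFAULT_MACROS.items()):
        macros = dict(zip(MACROMOLECULES[:-1], vals))
        macros["other"] = round(1.0 - sum(macros.values()), 6)
        entries.append(
            BiomassComposition(
                mu=mu,
                macromolecules=macros,
                monomer_demands=demands_from_macromolecules(macros),
            )
        )
    return CompositionTable(entries)


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    """Delimited text: one row per mu; macro fractions (g/gDCW) and per-drain
    monomer demands (mmol/gDCW, columns ``d_<drain>``)."""
    rows = []
    for e in table.entries:
        row = {"mu": e.mu}
        row.update({k: e.macromolecules.get(k, 0.0) for k in MACROMOLECULES})
        row.update({f"d_{rid}": e.monomer_demands.get(rid, 0.0) for rid in DRAIN_IDS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_composition_table(path: str | Path) -> CompositionTable:
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        macros = {k: float(row[k]) for k in MACROMOLECULES if k in row}
        demands = {
            c[2:]: float(row[c]) for c in df.columns if c.startswith("d_")
        }
        entries.append(
            BiomassComposition(
                mu=float(row["mu"]), macromolecules=macros, monomer_demands=demands
            )
        )
    return CompositionTable(entries)
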