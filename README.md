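# coliflux

Metabolic flux analysis (MFA) of *Escherichia coli* K-12 glucose-limited
continuous cultures — chemostat, A-stat (accelerostat, dilution rate rising
at a constant slow acceleration) and D-stat (constant dilution rate with
glucose–acetate co-feeding).

The package is for physiologists and bioprocess engineers who have culture
time series (dilution rate, biomass, substrate/by-product concentrations,
off-gas CO₂) and want a carefully closed carbon balance plus a fully
determined intracellular flux solution, including the energy side: how much
ATP the cells make, how much growth needs, and how much is *spilled*
(non-growth-associated dissipation, here dominated by the futile PTA-ACS
acetate cycle).

## The model

A lumped stoichiometric network of central carbon metabolism — glycolysis,
pentose phosphate pathway (PPP), TCA cycle with glyoxylate shunt, PEP
carboxylase anaplerosis (reversible, lumping Ppc/Pck), the acetate
excretion (Pta/AckA) and re-assimilation (Acs) branches, a pyrimidine
branch (aspartate + carbamoyl-phosphate → carbamoyl-aspartate (CBASP) →
dihydroorotate (DHO) → orotate), N-acetyl-aspartate (NAA) synthesis,
oxidative phosphorylation at a configurable P/O ratio, and an explicit
ATP-dissipation reaction. Only fluxes between branch points are modelled;
linear chains are lumped. The balanced species are 19 carbon metabolites
plus ATP, NADH and NADPH: a 22 × 50 stoichiometric matrix

    S v = 0,   v ∈ R⁵⁰,

with the 50 fluxes partitioned into 1 measured inflow (PTS glucose uptake,
which consumes PEP), 7 outflows fixed from measured excretion rates
(acetate, lactate, CBASP, DHO, orotate, NAA, CO₂), 18 biomass drains fixed
from a growth-rate-dependent biomass composition (flux = monomer demand × μ),
and 24 dependent fluxes. Two closure rules make the dependent system square:
the inactive branch of the mutually exclusive Pta/Acs pair is zero (switched
by the sign of net acetate exchange), and the glyoxylate shunt is coupled to
acetate assimilation (v_glyox = γ·v_Acs). The NADPH balance determines the
PPP split; the NADH balance determines respiration; the ATP balance
determines spilling. An unmeasured excess-carbon outflow from oxaloacetate
(`Vprod`) absorbs the carbon-balance gap of the measurements.

From each solved snapshot the package reports the energy ledger (total ATP
production, growth-associated ATP, ATP spilling, the glycolytic ATP fraction
and the TCA share of CO₂ and NADH production) and the carbon balance
(fractional recovery into biomass, CO₂ and every by-product, plus the
unclosed gap — recoveries + gap ≡ 1).

A synthetic-data module generates A-stat/D-stat/chemostat time series with
exact ground-truth flux vectors, emulating the key physiology of this
system: two-phase acetate overflow starting at μ ≈ 0.27 h⁻¹, three-phase
pyrimidine-intermediate excretion, total carbon wasting rising from 3 % to
11 % at constant biomass yield, and a D-stat minor-by-product wasting
plateau near 5.5 % regardless of co-utilisation capability.

## Worked example

Simulate an A-stat and run the whole pipeline:

```bash
coliflux simulate --regime astat --seed 101 --out astat.csv
coliflux all --timeseries astat.csv --out mfa_out --regime astat
```

or, equivalently, the numbered analysis drivers:

```bash
python analysis/01_simulate_scenarios.py
python analysis/02_specific_rates.py
python analysis/03_flux_solutions.py
python analysis/04_carbon_balance.py
python analysis/05_counterfactual_rerouting.py
python analysis/06_chemostat_comparison.py
```

which print, on the bundled reference scenario:

```
acetate overflow onset detected at mu = 0.266 1/h
biomass yield 0.459 +/- 0.003 g/g (constant within noise)
ATP spilling peaks at mu = 0.390 (13.20 mmol/gDCW/h) and declines to 9.64
  at mu = 0.491 (27% below the peak)
A-stat wasting rises 3.1% -> 11.2% of consumed carbon; gap reaches 4.8%
  at mu = 0.49
D-stat minor-by-product wasting ... mean 5.51% — similar across very
  different co-utilisation capabilities
at mu = 0.47 1/h, mis-assigning the wasted carbon to pyruvate shifts fluxes
  by: Ppc 18.1%, TCA (mean) 4.8%, Pdh 4.2%   (ordering Ppc > TCA > Pdh)
```

Reading: acetate overflow begins near μ = 0.27 h⁻¹; after the overflow
switch the culture excretes progressively more carbon as by-products
(3 → 11 % of consumed carbon) while the biomass yield stays constant, and
ATP spilling *falls* — the futile PTA-ACS cycle is disrupted, so less ATP is
dissipated even though growth accelerates. The counterfactual shows why
measuring the minor by-products matters: assigning the same wasted carbon
to a generic pyruvate outflow distorts anaplerosis most, then the TCA
cycle, then pyruvate dehydrogenase.

The `mfa_out/` bundle contains per-snapshot flux tables (50 reactions each,
with fixed/solved provenance), the energy ledger, carbon balances, wasting
profiles and a run log with residual diagnostics. `coliflux export-network`
writes the network as a documented text file or as SBML.

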