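# Methods

## Scope and model structure

`coliflux` solves a fully determined metabolic flux analysis for
glucose-limited *E. coli* K-12 continuous cultures. The network is a lumped
branch-point model: 50 reactions over 22 balanced species (19 carbon
metabolites plus the cofactor pools ATP, NADH, NADPH). The 50 fluxes split
into 1 measured inflow, 7 outflows, 18 biomass drains and 24 dependent
fluxes. Counting convention: the cofactor pools are included among the 22
balanced rows; external (boundary) species are not balanced.

Key structural choices, all visible in `data/default_network.txt`:

* **PTS uptake** consumes one PEP per glucose, which shifts the
  glycolysis/anaplerosis split relative to an ATP-driven uptake.
* **Lumping.** Glycolysis is four lumps (Pgi, Pfk·Fba·Tpi, GapA…Eno,
  Pyk); the oxidative PPP is one lump producing R5P + CO₂ + 2 NADPH; the
  non-oxidative PPP is two net transketolase/transaldolase lumps
  (2 R5P ⇌ F6P + E4P and R5P + E4P ⇌ F6P + GAP); the TCA segments are
  AcCoA+OAA→ICT, ICT→AKG (Icd, NADPH), and AKG→OAA (one lump including
  succinate dehydrogenase and malate dehydrogenase).
* **Redox bookkeeping.** Icd is NADP-linked; quinone-linked reducing
  equivalents (Sdh, dihydroorotate oxidase) are folded into the NADH pool
  at a discount factor (default 1.0, configurable). There is no
  transhydrogenase: the NADPH balance is an equation of the determined
  system and is what fixes the oxidative-PPP flux against biosynthetic
  NADPH demand. States with more Icd-NADPH than demand would need a
  negative PPP flux; the solver flags rather than clips such sign
  violations.
* **PEP ⇌ OAA** is a single reversible net exchange (Ppc forward, Pck
  reverse), because only net fluxes between branch points are modelled.
  Negative values (gluconeogenesis) occur during acetate co-utilisation.
* **PTA-ACS node.** Acetate excretion (Pta·AckA, +1 ATP) and
  re-assimilation (Acs, −2 ATP) are both present; at any snapshot the
  branch opposing the net measured acetate exchange is fixed to zero.
  Cycling below the overflow switch is therefore not resolved as separate
  Pta and Acs fluxes — its net effect, ATP dissipation, appears in the
  explicit spilling reaction.
* **Glyoxylate shunt** is tied to assimilation, v_glyox = γ·v_Acs with
  γ = 0.8 by default. A free shunt would make the assimilation regime
  underdetermined (it trades off against the excess-carbon outflow); γ was
  chosen within the physiologically active range such that all four
  default D-stat scenarios have feasible NADPH balances.
* **Vprod** is an unmeasured excess-carbon outflow from OAA and is a
  dependent flux: in the default "constraint" mode (CO₂ outflow fixed to
  the measured rate) it absorbs the carbon gap of the measurements. In
  "redundancy" mode Vprod is pinned to zero, the CO₂ outflow is solved
  from the CO₂ balance, and the solved-minus-measured CO₂ discrepancy is
  reported. The two modes answer the dual question "where does the
  unexplained carbon go: an unmeasured product, or mis-measured CO₂?".
* **ATP spilling** is an explicit dissipation reaction (ATP → ADP + Pᵢ),
  so it appears in the flux vector and in the rank accounting, and the ATP
  balance closes exactly by construction.

## Solving

Stoichiometry is exact rational; solving is floating point. The solver
fixes the inflow/outflow/drain fluxes and regime constraints, then solves a
square core (carbon + NADPH rows) and back-substitutes the pure-cofactor
tail: oxidative phosphorylation from the NADH row, spilling from the ATP
row. Consequences: the P/O ratio (default 2 mol ATP per NADH) scales only
the oxidative ATP term — every carbon flux is bit-identical under any P/O —
and the spilling/production ratio is the only energy quantity it moves.
Rank or balance failures raise errors that name the offending reaction or
the free directions; irreversible fluxes that come out negative are
flagged, never clipped. Residual tolerance for balances is 1e-6
(construction checks 1e-9); core condition numbers on the default network
are ~25.

## Specific rates

Chemostat: μ = D, algebraic balances averaged over a stationary window;
stationarity is asserted on the fitted linear trend of each series (default
threshold 5 % over the window). A-stat/D-stat: accumulation terms are kept
(μ = D + X′/X, q_P = (P′ + D·(P − P_feed))/X, q_S = (D·(S_feed − S) − S′)/X)
with derivatives from a centred local linear regression (default 11
samples); the biomass trend uses a 3× wider window because biomass is the
slowest, noisiest channel and its slope enters μ directly. The CO₂ signal
is smoothed with the same local regression. Excretion is positive,
consumption negative (acetate is negative under D-stat co-feeding); glucose
uptake is positive.

Overflow-onset detection gates on sustained excretion above a threshold
(default 0.05 mmol gDCW⁻¹ h⁻¹), then back-extrapolates the per-biomass
production q/μ — linear in μ for a ramping onset — to its zero crossing,
which removes the threshold-lag bias; it falls back to the gate μ for step
profiles or unusable fits.

## Biomass composition and drains

The shipped composition table is a surrogate assembled from
literature-typical E. coli K-12 values: protein falling from 0.61 to
0.52 g/gDCW and RNA rising from 0.14 to ~0.21 g/gDCW as μ grows, levelling
near μ = 0.40 h⁻¹; DNA, lipid, LPS, murein and glycogen constant. It is not
a measured dataset and is user-replaceable (same columns). Mass fractions
convert to per-drain monomer demands through average monomer masses and
family shares; each of the 18 drain reactions carries precursor and
cofactor stoichiometry, and drain flux = demand × μ. Pyrimidine nucleotides
for RNA/DNA draw on orotate through the pyrimidine branch, which couples
nucleotide demand to the strain's CBASP/DHO/orotate bottleneck. One drain
(`BmAssembly`) is a pure ATP sink representing growth-associated demand
beyond monomer synthesis (transport, turnover, assembly); its default is
set so the total growth-associated ATP requirement is ≈95 mmol gDCW⁻¹,
i.e. an observed aerobic growth Y_ATP of ≈10.5 g/mol rather than the
theoretical minimum. Biomass carbon content computed from the drains is
46–48 % by mass across the table (sanity envelope 35–55 % enforced in
tests). Growth-associated cofactor demands are a derived view of the drain
stoichiometry, not an independent input.

## Synthetic scenarios and what they do (not) show

The generator emulates the study conditions: A-stat acceleration
0.01 h⁻², μ from 0.10 to 0.48 h⁻¹, feed glucose 25 mM (≈4.5 g/L), constant
biomass yield 0.46 g/g, acetate overflow onset 0.27 h⁻¹ with a steep second
phase beyond 0.46 h⁻¹, total wasting 3 → 11 % of consumed carbon, D-stats
at D = 0.10/0.24/0.30/0.45 h⁻¹ with co-utilisation capabilities 0.82/0.57/
0.46/0.19 and a 5.5 % minor-by-product wasting plateau. The minor-species
profiles (CBASP, DHO, orotate, NAA, lactate) interpolate published
per-biomass production levels at four growth rates
(`data/byproduct_reference.csv`); acetate carries the remaining wasting so
the endpoints hit the configured fractions exactly. The measured carbon
balance is deliberately left unclosed at high μ: a ground-truth Vprod flux
rises from zero at the overflow onset to 5 % of carbon in at the ramp top.
This reproduces the characteristic unclosed balance of such datasets and is
also what makes computed ATP production — and hence spilling — decline
after the overflow switch at constant yield. The ramp continues a small
margin (default 0.03 h⁻¹) beyond the analysis range with the by-product
fractions held at their ramp-top values, so that rates at μ_max itself can
be estimated from interior data.

Ground-truth flux vectors are built by fixing the profile-implied exchange
fluxes and solving the network with the CO₂ outflow free, so they satisfy
every balance exactly; measured concentration series come from integrating
the reactor balances (`solve_ivp`, tolerance 1e-10) and multiplying by
log-normal noise (default CV 2 %, seeded, mean-one). The generator rejects
configurations whose implied fluxes are unphysical (negative respiration,
spilling or PPP flux).

What passing tests show: the pipeline is exact on noise-free data, degrades
gracefully under multiplicative measurement noise, and recovers the
physiological parameters that generated the data. What they do not show:
anything about kinetics or regulation (profiles are parametric, not
mechanistic), about real measurement error structure (no drift,
autocorrelation or species-specific analytics bias), or about the accuracy
of the surrogate biomass composition for a real culture.

## Numerical conventions and tolerances

* Exact-recovery checks: 1e-8 relative (achieved ~1e-15); conservation:
  carbon gap ≤1e-9, ATP closure ≤1e-6.
* Noisy-recovery metric: flux profiles over the ramp are compared after a
  5-snapshot rolling mean (the analogue of averaging replicate
  cultivations); per reaction, the RMS of the relative error (absolute
  floor: 5 % of the largest flux, so near-zero fluxes are not scored on
  relative terms) must stay within 5 %. Single unsmoothed snapshots carry
  ~3× larger errors on difference quantities (spilling, Vprod), which is
  inherent noise amplification, not solver error.
* Quasi-steady rate estimation is bias-limited in the steep second acetate
  phase (beyond μ ≈ 0.46 h⁻¹, concentration e-folding becomes comparable
  to the regression window); instantaneous rates there are only reliable
  to ~10 %, and the tests assert the 2 % recovery below that breakpoint.
* Problem sizes: the default suite and the acceptance script analyze one
  165-sample A-stat and four 97-sample D-stats, solve ~40–80 snapshot
  systems per check and 100 randomized oracle comparisons; the whole
  acceptance run completes in seconds.

## Known limitations

* The 22×50 determinedness relies on the two closure rules; a user network
  without a Pta/Acs pair or glyoxylate coupling must supply its own ties.
* Acetate cycling below the overflow switch is observationally equivalent
  to ATP spilling in this framework and is reported as such.
* NADPH states richer than biosynthetic demand (high TCA flux at very low
  growth) are flagged as infeasible rather than balanced by a
  transhydrogenase.
* The SBML export is one-way (no importer) and encodes the lumped model,
  not a genome-scale reconstruction.
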