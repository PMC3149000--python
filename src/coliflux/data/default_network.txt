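# coliflux network file
# metabolite: id | name | carbon_atoms | kind(balanced/cofactor/external)
# reaction:   id | equation | role | reversible|irreversible | lumped:a,b
po_ratio = 2.0
fadh2_discount = 1.0
glyoxylate_coupling = 0.8

[metabolites]
G6P | glucose-6-phosphate | 6 | balanced
F6P | fructose-6-phosphate | 6 | balanced
GAP | glyceraldehyde-3-phosphate | 3 | balanced
PEP | phosphoenolpyruvate | 3 | balanced
PYR | pyruvate | 3 | balanced
ACCOA | acetyl-CoA (acetyl carbon) | 2 | balanced
ACE | acetate (intracellular pool) | 2 | balanced
OAA | oxaloacetate | 4 | balanced
ICT | isocitrate | 6 | balanced
AKG | 2-oxoglutarate | 5 | balanced
R5P | ribose-5-phosphate | 5 | balanced
E4P | erythrose-4-phosphate | 4 | balanced
ASP | aspartate | 4 | balanced
CAP | carbamoyl-phosphate | 1 | balanced
CBASP | carbamoyl-aspartate | 5 | balanced
DHO | dihydroorotate | 5 | balanced
ORO | orotate | 5 | balanced
NAA | N-acetyl-aspartate | 6 | balanced
CO2 | carbon dioxide | 1 | balanced
ATP | ATP (net high-energy phosphate) | 0 | cofactor
NADH | NADH (incl. folded quinone equivalents) | 0 | cofactor
NADPH | NADPH | 0 | cofactor
GLC_ext | glucose (feed) | 6 | external
ACE_ext | acetate (broth) | 2 | external
LAC_ext | lactate (broth) | 3 | external
CBASP_ext | carbamoyl-aspartate (broth) | 5 | external
DHO_ext | dihydroorotate (broth) | 5 | external
ORO_ext | orotate (broth) | 5 | external
NAA_ext | N-acetyl-aspartate (broth) | 6 | external
CO2_ext | carbon dioxide (off-gas) | 1 | external
VPROD_ext | excess-carbon outflow from oxaloacetate | 4 | external
BIOMASS | biomass macromolecule sink | 0 | external

[reactions]
Pts | 1 GLC_ext + 1 PEP -> 1 G6P + 1 PYR | measured_inflow | irreversible | lumped:PtsGHI,Glk
Pgi | 1 G6P <-> 1 F6P | dependent | reversible
Pfk | 1 F6P + 1 ATP -> 2 GAP | dependent | irreversible | lumped:PfkA,FbaA,TpiA
Emp | 1 GAP -> 1 PEP + 1 ATP + 1 NADH | dependent | irreversible | lumped:GapA,Pgk,GpmA,Eno
Pyk | 1 PEP -> 1 PYR + 1 ATP | dependent | irreversible
Pdh | 1 PYR -> 1 ACCOA + 1 CO2 + 1 NADH | dependent | irreversible
Zwf | 1 G6P -> 1 R5P + 1 CO2 + 2 NADPH | dependent | irreversible | lumped:Zwf,Pgl,Gnd,Rpi
TktA | 2 R5P <-> 1 F6P + 1 E4P | dependent | reversible | lumped:TktA,TalB
TktB | 1 R5P + 1 E4P <-> 1 F6P + 1 GAP | dependent | reversible | lumped:TktB,TalA
GltA | 1 ACCOA + 1 OAA -> 1 ICT | dependent | irreversible | lumped:GltA,AcnB
Icd | 1 ICT -> 1 AKG + 1 CO2 + 1 NADPH | dependent | irreversible
SucAB | 1 AKG -> 1 OAA + 1 CO2 + 1 ATP + 3 NADH | dependent | irreversible | lumped:SucAB,SucCD,SdhABCD,FumA,Mdh
Ppc | 1 PEP + 1 CO2 <-> 1 OAA | dependent | reversible | lumped:Ppc,PckA
AceAB | 1 ICT + 1 ACCOA -> 2 OAA + 3 NADH | dependent | irreversible | lumped:AceA,AceB,SdhABCD,FumA,Mdh
Pta | 1 ACCOA -> 1 ACE + 1 ATP | dependent | irreversible | lumped:Pta,AckA
Acs | 1 ACE + 2 ATP -> 1 ACCOA | dependent | irreversible
Vprod | 1 OAA -> 1 VPROD_ext | dependent | irreversible
CarAB | 1 CO2 + 2 ATP -> 1 CAP | dependent | irreversible
PyrB | 1 ASP + 1 CAP -> 1 CBASP | dependent | irreversible
PyrC | 1 CBASP -> 1 DHO | dependent | irreversible
PyrD | 1 DHO -> 1 ORO + 1 NADH | dependent | irreversible
AspC | 1 OAA + 1 NADPH -> 1 ASP | dependent | irreversible | lumped:GdhA,AspC
YjgM | 1 ASP + 1 ACCOA -> 1 NAA | dependent | irreversible
Oxp | 1 NADH -> 2 ATP | dependent | irreversible | lumped:Nuo,Cyo,AtpABC
AtpD | 1 ATP -> (none) | dependent | irreversible
AceOut | 1 ACE <-> 1 ACE_ext | outflow | reversible
LacOut | 1 PYR + 1 NADH -> 1 LAC_ext | outflow | irreversible | lumped:LdhA
CbaspOut | 1 CBASP -> 1 CBASP_ext | outflow | irreversible
DhoOut | 1 DHO -> 1 DHO_ext | outflow | irreversible
OroOut | 1 ORO -> 1 ORO_ext | outflow | irreversible
NaaOut | 1 NAA -> 1 NAA_ext | outflow | irreversible
Co2Out | 1 CO2 -> 1 CO2_ext | outflow | irreversible
BmAla | 1 PYR + 1 NADPH + 43/10 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmVli | 2 PYR + 2 NADPH + 43/10 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmSer | 1 GAP + 1 NADPH + 43/10 ATP -> 1 NADH + 1 BIOMASS | biomass_drain | irreversible
BmAsp | 1 OAA + 2 NADPH + 24/5 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmGlu | 1 AKG + 2 NADPH + 47/10 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmAro | 1 E4P + 2 PEP + 2 NADPH + 22/5 ATP -> 1 CO2 + 1 BIOMASS | biomass_drain | irreversible
BmHis | 1 R5P + 1 NADPH + 6 ATP -> 1 NADH + 1 BIOMASS | biomass_drain | irreversible
BmRnaPur | 1 R5P + 4/3 GAP + 1 CO2 + 1/2 NADPH + 6 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmRnaPyr | 1 R5P + 1 ORO + 2/5 NADPH + 17/5 ATP -> 1 CO2 + 1 BIOMASS | biomass_drain | irreversible
BmDnaPur | 1 R5P + 4/3 GAP + 1 CO2 + 3/2 NADPH + 7 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmDnaPyr | 1 R5P + 1 ORO + 7/5 NADPH + 4 ATP -> 1 CO2 + 1 BIOMASS | biomass_drain | irreversible
BmAcyl | 8 ACCOA + 14 NADPH + 7 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmGlyc3P | 1 GAP + 1 NADH + 1/2 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmLps | 1 G6P + 1/2 NADPH + 2 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmMurein | 1 F6P + 1/2 PEP + 2/5 OAA + 3/10 PYR + 1/2 NADPH + 2 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmGlycogen | 1 G6P + 1 ATP -> 1 BIOMASS | biomass_drain | irreversible
BmC1 | 1 GAP + 1/2 NADPH + 1 ATP -> 1 NADH + 1 BIOMASS | biomass_drain | irreversible
BmAssembly | 1 ATP -> 1 BIOMASS | biomass_drain | irreversible
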