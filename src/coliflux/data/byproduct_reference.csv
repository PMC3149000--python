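# Steady-state by-product levels per biomass (mmol / g DCW) of E. coli K-12
# MG1655 glucose-limited continuous cultures at four specific growth rates,
# measured in chemostat and A-stat regimes. Empty cells: not detected.
species,mu,chemostat,astat_mean,astat_sd
CBASP,0.10,0.188,0.139,0.047
CBASP,0.24,0.089,0.218,0.018
CBASP,0.30,0.195,0.268,0.026
CBASP,0.45,0.188,0.299,0.026
DHO,0.10,0.131,0.146,0.021
DHO,0.24,0.117,0.181,0.043
DHO,0.30,0.091,0.135,0.029
DHO,0.45,0.065,0.078,0.008
lactate,0.10,,0.021,0.005
lactate,0.24,0.034,0.041,0.003
lactate,0.30,0.034,0.049,0.006
lactate,0.45,0.046,0.059,0.002
NAA,0.10,,,
NAA,0.24,0.006,,
NAA,0.30,0.034,0.057,0.013
NAA,0.45,0.069,0.111,0.021
orotate,0.10,0.091,0.137,0.047
orotate,0.24,0.193,0.171,0.041
orotate,0.30,0.115,0.171,0.037
orotate,0.45,0.344,0.229,0.012
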