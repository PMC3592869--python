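# Segment polarity network, variant: single_cell_merged_inputs
targets, factors
SLP, SLP
wg, (CIA & SLP & !CIR) | (wg & (CIA | SLP) & !CIR)
WG, wg
en, (nWG) & !SLP
EN, en
hh, EN & !CIR
HH, hh
ptc, CIA & !EN & !CIR
PTC, ptc | (PTC & !(nHH))
PH, PTC & (nHH)
SMO, !PTC | (nHH)
ci, !EN
CI, ci
CIA, CI & (!PTC | (nHH) | (nHH))
CIR, CI & PTC & !(nHH) & !(nHH)
nWG, nWG
nHH, nHH
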