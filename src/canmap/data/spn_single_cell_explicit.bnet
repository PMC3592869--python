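# Segment polarity network, variant: single_cell_explicit
targets, factors
SLP, SLP
wg, (CIA & SLP & !CIR) | (wg & (CIA | SLP) & !CIR)
WG, wg
en, (WG_prev | WG_next) & !SLP
EN, en
hh, EN & !CIR
HH, hh
ptc, CIA & !EN & !CIR
PTC, ptc | (PTC & !(HH_prev | HH_next))
PH, PTC & (HH_prev | HH_next)
SMO, !PTC | (HH_prev | HH_next)
ci, !EN
CI, ci
CIA, CI & (!PTC | (HH_prev | HH_next) | (hh_prev | hh_next))
CIR, CI & PTC & !(HH_prev | HH_next) & !(hh_prev | hh_next)
WG_prev, WG_prev
WG_next, WG_next
HH_prev, HH_prev
HH_next, HH_next
hh_prev, hh_prev
hh_next, hh_next
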