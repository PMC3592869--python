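# Segment polarity network, variant: parasegment_4cell
targets, factors
SLP_1, SLP_1
wg_1, (CIA_1 & SLP_1 & !CIR_1) | (wg_1 & (CIA_1 | SLP_1) & !CIR_1)
WG_1, wg_1
en_1, (WG_4 | WG_2) & !SLP_1
EN_1, en_1
hh_1, EN_1 & !CIR_1
HH_1, hh_1
ptc_1, CIA_1 & !EN_1 & !CIR_1
PTC_1, ptc_1 | (PTC_1 & !(HH_4 | HH_2))
PH_1, PTC_1 & (HH_4 | HH_2)
SMO_1, !PTC_1 | (HH_4 | HH_2)
ci_1, !EN_1
CI_1, ci_1
CIA_1, CI_1 & (!PTC_1 | (HH_4 | HH_2) | (hh_4 | hh_2))
CIR_1, CI_1 & PTC_1 & !(HH_4 | HH_2) & !(hh_4 | hh_2)
SLP_2, SLP_2
wg_2, (CIA_2 & SLP_2 & !CIR_2) | (wg_2 & (CIA_2 | SLP_2) & !CIR_2)
WG_2, wg_2
en_2, (WG_1 | WG_3) & !SLP_2
EN_2, en_2
hh_2, EN_2 & !CIR_2
HH_2, hh_2
ptc_2, CIA_2 & !EN_2 & !CIR_2
PTC_2, ptc_2 | (PTC_2 & !(HH_1 | HH_3))
PH_2, PTC_2 & (HH_1 | HH_3)
SMO_2, !PTC_2 | (HH_1 | HH_3)
ci_2, !EN_2
CI_2, ci_2
CIA_2, CI_2 & (!PTC_2 | (HH_1 | HH_3) | (hh_1 | hh_3))
CIR_2, CI_2 & PTC_2 & !(HH_1 | HH_3) & !(hh_1 | hh_3)
SLP_3, SLP_3
wg_3, (CIA_3 & SLP_3 & !CIR_3) | (wg_3 & (CIA_3 | SLP_3) & !CIR_3)
WG_3, wg_3
en_3, (WG_2 | WG_4) & !SLP_3
EN_3, en_3
hh_3, EN_3 & !CIR_3
HH_3, hh_3
ptc_3, CIA_3 & !EN_3 & !CIR_3
PTC_3, ptc_3 | (PTC_3 & !(HH_2 | HH_4))
PH_3, PTC_3 & (HH_2 | HH_4)
SMO_3, !PTC_3 | (HH_2 | HH_4)
ci_3, !EN_3
CI_3, ci_3
CIA_3, CI_3 & (!PTC_3 | (HH_2 | HH_4) | (hh_2 | hh_4))
CIR_3, CI_3 & PTC_3 & !(HH_2 | HH_4) & !(hh_2 | hh_4)
SLP_4, SLP_4
wg_4, (CIA_4 & SLP_4 & !CIR_4) | (wg_4 & (CIA_4 | SLP_4) & !CIR_4)
WG_4, wg_4
en_4, (WG_3 | WG_1) & !SLP_4
EN_4, en_4
hh_4, EN_4 & !CIR_4
HH_4, hh_4
ptc_4, CIA_4 & !EN_4 & !CIR_4
PTC_4, ptc_4 | (PTC_4 & !(HH_3 | HH_1))
PH_4, PTC_4 & (HH_3 | HH_1)
SMO_4, !PTC_4 | (HH_3 | HH_1)
ci_4, !EN_4
CI_4, ci_4
CIA_4, CI_4 & (!PTC_4 | (HH_3 | HH_1) | (hh_3 | hh_1))
CIR_4, CI_4 & PTC_4 & !(HH_3 | HH_1) & !(hh_3 | hh_1)
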