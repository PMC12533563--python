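# Colorectal cancer screening panel: fecal immunochemical test (FIT),
# multitarget stool DNA (MTsDNA), and colonoscopy (COL).  Accuracy and cost
# data from Pickhardt et al. (2003) and Ladabaum & Mannalithara (2016).
# Colonoscopy harm: 0.04% perforation rate x 7.5% mortality x 15 remaining
# life years ~ 6e-4 QALY.  Treatment: cRx = USD 75000, lambda = USD 100000
# per QALY, qg = 1.5 QALY, so b = lambda*qg - cRx = USD 75000.  The
# trade-off rho is left free (it varies across patients and analyses).
name: colorectal
frame:
  benefit: 75000
  willingness_lambda: 100000
  qaly_gain: 1.5
  treatment_cost: 75000
tests:
  - {name: FIT, sensitivity: 0.733, specificity: 0.964, cost: 19}
  - {name: MTsDNA, sensitivity: 0.933, specificity: 0.898, cost: 649}
  - {name: COL, sensitivity: 0.887, specificity: 0.796, cost: 1400, harm: 6.0e-4}
notes:
  FIT: "Se/Sp and USD 19 cost: Ladabaum & Mannalithara 2016"
  MTsDNA: "Se/Sp and USD 649 cost: Ladabaum & Mannalithara 2016"
  COL: "Se/Sp: Pickhardt et al. 2003; USD 1400 cost and perforation-derived 6e-4 QALY harm"
  frame.benefit: "b = lambda*qg - cRx = 100000*1.5 - 75000 = USD 75000"
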