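# Prostate cancer testing panel: free-to-total PSA ratio (FT, positive below
# a 20% cutoff), human kallikrein 2 (hK2, positive above 0.075 ng/mL), and
# transrectal ultrasound (TRUS, positive above 50 cm^3).  Operating points
# from Vickers et al. (2013), a biopsy cohort with elevated PSA.  Utilities
# are supplied as ratios to the treatment benefit b: the invasive TRUS is
# taken to cost one tenth of b, the blood markers one hundredth.  The
# reference trade-off rho = 0.26 matches the cohort's cancer positivity rate.
name: prostate
frame:
  rho: 0.26
tests:
  - {name: FT, sensitivity: 0.91, specificity: 0.40, loss_over_b: 0.01}
  - {name: hK2, sensitivity: 0.51, specificity: 0.78, loss_over_b: 0.01}
  - {name: TRUS, sensitivity: 0.84, specificity: 0.34, loss_over_b: 0.1}
notes:
  FT.sensitivity: "Vickers et al. 2013, free-to-total PSA at 20% cutoff"
  FT.specificity: "Vickers et al. 2013, free-to-total PSA at 20% cutoff"
  hK2.sensitivity: "Vickers et al. 2013, hK2 at 0.075 ng/mL cutoff"
  hK2.specificity: "Vickers et al. 2013, hK2 at 0.075 ng/mL cutoff"
  TRUS.sensitivity: "Vickers et al. 2013, TRUS volume at 50 cm^3 cutoff"
  TRUS.specificity: "Vickers et al. 2013, TRUS volume at 50 cm^3 cutoff"
  TRUS.loss_over_b: "b set to 10x the TRUS loss, after a urologist's stated willingness to run at most 10 ultrasounds per cancer found"
  FT.loss_over_b: "blood markers taken as 10x cheaper/less burdensome than TRUS"
  hK2.loss_over_b: "blood markers taken as 10x cheaper/less burdensome than TRUS"
  frame.rho: "26% biopsy positivity in the Vickers et al. 2013 cohort, used as reference trade-off"
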