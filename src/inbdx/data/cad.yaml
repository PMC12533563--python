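# Stable coronary artery disease panel: exercise treadmill testing (ETT),
# stress echocardiography (SE), myocardial perfusion scintigraphy (MPS),
# and coronary CT angiography (CCTA).  Accuracy and cost data from
# Min et al. (2017).  Treatment: l = USD 55000 (average treatment cost for
# patients at 20% pre-test probability), b = USD 105000.  Threshold
# reproductions calibrate b/l = 1.9 exactly (rho = 1/2.9), which puts the
# ETT test threshold at 15% to match the 2013 ESC guideline floor.
# MPS is dominated by SE on sensitivity, specificity and cost alike.
name: cad
frame:
  benefit: 105000
  loss: 55000
tests:
  - {name: ETT, sensitivity: 0.68, specificity: 0.77, cost: 100}
  - {name: SE, sensitivity: 0.867, specificity: 0.807, cost: 340}
  - {name: MPS, sensitivity: 0.806, specificity: 0.747, cost: 819}
  - {name: CCTA, sensitivity: 0.937, specificity: 0.847, cost: 394}
notes:
  ETT: "Se/Sp and USD 100 cost: Min et al. 2017"
  SE: "Se/Sp and USD 340 cost: Min et al. 2017"
  MPS: "Se/Sp and USD 819 cost: Min et al. 2017; dominated by SE throughout"
  CCTA: "Se/Sp and USD 394 cost: Min et al. 2017 (component values are primary; derived cost ratio ~3.75e-3)"
  frame: "l = USD 55000, b = USD 105000 (Min et al. 2017); calibration b/l = 1.9 for threshold analyses"
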