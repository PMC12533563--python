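# inbdx — incremental net benefit of single and combined diagnostic tests

`inbdx` answers a clinical decision question: given a patient's pre-test
probability of disease *p* and the trade-off between the benefit *b* of
treating a diseased patient and the loss *l* of treating a healthy one,
which diagnostic test — or which ordered combination of tests — is worth
running, and in what sequence?  It is aimed at health economists,
clinical-guideline developers, and methodologists working in medical
decision analysis.

## The model

A treatment is characterized by its benefit *b = λq_g − c_Rx* and loss
*l = λq_l + c_Rx* (λ: willingness to pay per QALY, *q_g/q_l*: QALY
gain/loss, *c_Rx*: treatment cost), summarized by the trade-off
ρ = l/(l+b), which equals the treatment-threshold probability: treat
without testing iff p ≥ ρ.

A binary test with sensitivity Se and specificity Sp contributes a value of
diagnostic information (in units of *b*, with r = ρ/(1−ρ)):

    VI(p, ρ) = p·Se − (1−p)(1−Sp)·r        if p < ρ   (default: no treatment)
             = −p(1−Se) + (1−p)·Sp·r       if p ≥ ρ   (default: treatment)

and an incremental net benefit INB = VI − l_Dx/b, where l_Dx = λq_h + c_Dx
is the test's own harm-plus-cost loss.  Testing is indicated where
INB > 0; solving INB = 0 per branch yields the classical test threshold
p_Dx and test-treatment threshold p̄_Dx in closed form.

Multiple conditionally independent tests combine under three positivity
rules — conjunctive (AND: treat only if all positive; stop at the first
negative), disjunctive (OR: treat if any positive; stop at the first
positive), and majority (odd panels; stop once one side holds a strict
majority).  The composite operating point is order-invariant
(e.g. Se_AND = ∏Se_i, Sp_AND = 1 − ∏(1−Sp_i)); only the *expected testing
loss* — each test's loss weighted by the probability it is actually
administered — depends on the sequence.  The optimal protocol at (p, ρ) is
the argmax of INB over all enumerated protocols, and rasterizing that
argmax over the unit square yields decision-region maps.  A ROC view
flags which composite operating points sit on the upper convex hull
(informationally efficient) — which, once costs enter, need not coincide
with INB-optimality.

## Worked example

Three packaged case studies (`prostate`, `colorectal`, `cad`) carry the
published operating points, costs and harms of real test panels.  For the
prostate panel (free-to-total PSA "FT", human kallikrein 2 "hK2",
transrectal ultrasound "TRUS"; losses 0.01/0.01/0.1 in units of *b*,
reference trade-off ρ = 0.26):

```sh
$ inbdx evaluate --case prostate --protocol "hK2&FT" --p 0.2 --rho 0.26
protocol hK2&FT: Se=0.4641 Sp=0.8680
INB(p=0.2, rho=0.26) = 0.042937 (units of b)
best action here: TEST with hK2&FT (INB=0.042937)
```

The conjunctive pair run hK2-first has composite sensitivity
0.51·0.91 = 0.4641 and specificity 1 − 0.22·0.60 = 0.868; at p = 0.2 its
INB of ≈ 0.043·b is the best of all 33 protocols, so a patient at 20%
risk should get hK2 and, only if it is positive, FT.

```sh
$ inbdx thresholds --case prostate --rho 0.26
  FT        p_test=0.1970  p_test_treat=0.5662
  hK2       p_test=0.1486  p_test_treat=0.3456
  TRUS      p_test=-       p_test_treat=-
  hK2&FT    p_test=0.1154  p_test_treat=0.3470
  FT|hK2    p_test=0.2130  p_test_treat=0.6348
  ...
overall testing range at rho=0.26: [0.1154, 0.6348]
```

Below p ≈ 0.12 no protocol is worth its cost (do not test, do not treat);
above p ≈ 0.63 treat without testing; TRUS alone is never indicated at
this ρ.  `inbdx map --case prostate --grid 501 --out map.csv --png map.png`
rasterizes the full (p, ρ) decision regions, and
`inbdx roc --case colorectal` reports the 12 distinct operating points of
the colorectal panel, 5 of which form the ROC frontier (none of them a
single test).

The same analyses run on user panels via `--config panel.yaml` (schema:
a `frame` mapping with `benefit`/`loss`/`rho`, and a `tests` list with
`name`, `sensitivity`, `specificity`, `cost`, `harm` or a direct
`loss_over_b`).

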