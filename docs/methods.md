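# Methods

This note documents the models and procedures implemented in
`airwaydx`, the parameters that matter, the numerical choices, and the
known limitations — in particular what the synthetic cohort generator
does and does not emulate.

## Fuzzy interpretation of IOS measurements

Four quantities drive the rule base: R5 and R20 in percent of
predicted, the reactance deficit d = X5pred − X5 in kPa/(L/s), and the
resistance difference ΔR = R5 − R20 in kPa/(L/s). Each is mapped to
linguistic degrees by piecewise-linear membership functions:

| term | shape | breakpoints |
|---|---|---|
| μ_normal(R), μ_high(R) | complementary shoulders | 150 → 155 %pred |
| μ_normal(d), μ_high(d) | complementary shoulders | 0.15 → 0.155 kPa/(L/s) |
| μ_none(ΔR) | descending shoulder | 0 → 0.05 kPa/(L/s) |
| μ_min(ΔR) | triangle | 0.05, 0.125, 0.2 kPa/(L/s) |
| μ_sig(ΔR) | ascending shoulder | 0.2 → 0.35 kPa/(L/s) |

Two conventions needed fixing where the source material for this rule
family is ambiguous or internally inconsistent:

- **Units.** The resistance memberships take % of predicted (their
  breakpoints sit at the 150 %pred clinical limit), whereas the ΔR
  memberships take absolute kPa/(L/s) (0.05–0.35 are physiologic
  absolute values). This is the only dimensionally coherent split.
- **μ_min above 0.2.** A naive transcription of the triangle's falling
  limb can be written so that it is negative on its own support and
  saturates at 1 beyond 0.2, which would contradict μ_sig. We use the
  standard triangle (0.05, 0.125, 0.2) with value 0 above 0.2.
- **Reactance sign.** X5 is stored as measured (typically negative);
  the criterion quantity is the deficit d = X5pred − X5, positive when
  reactance is more negative than predicted, so a single ascending
  threshold applies.

The rule base (AND = min T-norm, OR = max):

1. R5 normal ∧ R20 normal ∧ ΔR none ∧ X5 normal → NSCO-SV
2. R5 normal ∧ R20 normal ∧ ΔR min ∧ X5 normal → NSCO-DV
3. R5 normal ∧ R20 normal ∧ ΔR sig ∧ X5 normal → NSPO
4. R5 high ∧ R20 high ∧ ΔR none ∧ X5 normal → CO-SV
5. R5 high ∧ R20 high ∧ (ΔR min ∨ X5 normal ∨ X5 high) → CO-DV
6. R5 high ∧ R20 high ∧ ΔR sig ∧ X5 high → PO

**Rule 5 connective.** Rule 5 mixes AND and OR. Reading it with AND
binding tighter than OR — `(R5 high ∧ R20 high ∧ ΔR min) ∨ X5 normal ∨
X5 high` — makes the rule fire at degree ≥ 0.5 on *every* input,
because the X5 pair is complementary; the crisp-normal case would then
never classify as NSCO-SV. We therefore nest the OR group inside the
AND chain: `min(R5 high, R20 high, max(ΔR min, X5 normal, X5 high))`.
This is the only self-consistent reading; crisply it reduces to
"central obstruction with any ΔR/X5 combination", and the X5
alternatives are vacuous for crisp inputs (an oddity of the rule as
stated, preserved deliberately).

The output label is the argmax of the six activations. Ties are broken
toward the clinically more severe pattern (PO > CO-DV > CO-SV > NSPO >
NSCO-DV > NSCO-SV), a conservative choice that prefers detecting
obstruction; with the distributions used here ties occur only on
degenerate (all-zero or crisp-overlapping) inputs. There is no
defuzzification to a number — the output is categorical plus its
activation vector.

All breakpoints are exposed in the YAML `fuzzy:` config block.

## Static criteria and challenge tests

All comparisons are strict inequalities; boundary values fail.

- Asthma (static): asthma symptoms ∧ R5 > 150 %pred ∧ R20 > 150 %pred
  ∧ d > 0.15 ∧ FEV1/FVC < 0.8.
- COPD (static): COPD symptoms ∧ exposure history ∧ age > 40 ∧
  R5 > 150 %pred ∧ d > 0.15 ∧ FEV1/FVC < 0.7.
- BDT (salbutamol 400 µg, one post measurement): positive iff R5 falls
  by more than 25 %, |X5| falls by more than 20 %, and FEV1 *improves*
  by more than 12 % of baseline **and** more than 200 mL (all three
  clauses required). The FEV1 clause direction follows bronchodilator
  pharmacology and the international reversibility guidelines: a
  bronchodilator that helps raises FEV1.
- BPT (serial methacholine doses): positive at the first dose whose
  FEV1 is at or below 80 % of baseline (the conventional PC20
  boundary counts as positive); doses after the trigger are ignored.
  No interpolation between doses is attempted.

## Diagnosis workflow

Static → BDT → BPT, with each diagnosis carrying its step and a full
trace:

- **STATIC:** COPD criteria are checked before asthma. When both fire
  (possible when FEV1/FVC < 0.7 and both symptom sets are positive) the
  patient gets COPD — the stricter ratio threshold belongs to COPD —
  and the trace records the arbitration. A patient with a sub-central
  fuzzy pattern (NSCO-SV/NSCO-DV), FEV1/FVC ≥ 0.8 and no positive
  symptom set is healthy. Everything else is nonspecific.
- **POST_BDT:** positive reversibility with asthma symptoms → asthma;
  negative reversibility with the full COPD gate (symptoms, exposure,
  age > 40, ratio < 0.7) → COPD.
- **POST_BPT:** hyperreactivity → asthma; none → healthy.

A nonspecific report lacking the required challenge series raises an
explicit referral error naming the missing test rather than forcing a
guess — mirroring the clinical hand-off to bronchial-hyperreactivity
testing.

The trained network is *recorded* alongside each diagnosis (its three
output scores) but the rule pathway is authoritative: the printed
decision criteria are fully deterministic, and keeping them in charge
keeps every criterion directly testable. This arbitration was a
genuinely open design point; the rule-authoritative choice is ours.

## Neural classifier

The 15-dimensional feature vector is: the six rule activations, R5 and
R20 %pred divided by 100, the reactance deficit, ΔR, FEV1 %pred divided
by 100, FEV1/FVC, and three 0/1 flags (asthma symptoms, COPD symptoms
with exposure, age > 40). The exact composition of the input vector was
not prescribed by the clinical decision rules; this one passes through
everything the rules consume, on a roughly unit scale.

Architecture: one tansig (hyperbolic tangent) hidden layer, default 10
units (configurable), three linear outputs fitted to one-hot targets by
sum-of-squared error — a regression-style readout with argmax
classification, ties broken by class order (asthma, copd, healthy).

Training is Levenberg–Marquardt on the full analytic Jacobian:
(JᵀJ + λI)δ = −Jᵀe, initial damping λ = 1e-3, ×10 on a rejected step,
÷10 on acceptance, cap 1e10, at most 200 iterations, gradient tolerance
1e-8, SSE tolerance 1e-12. Accepted steps never increase the SSE (the
training record asserts this). Weights initialize uniformly in
[−0.5, 0.5] from a seeded generator; the seed is a required, logged
parameter and runs are bit-reproducible. The optimizer core is generic
(residual + Jacobian callbacks), which lets the test suite verify it
against closed-form linear least squares in the linear limit and
against an independent optimizer on a toy problem.

The stratified estimation/validation split allocates
round(n·fraction) records to estimation using largest-remainder
apportionment across classes: overall sizes are exact (1000 at 0.8 →
800/200) while per-class counts stay proportional (437/438/125 → 350/
350/100). Each class keeps at least one record on each side.

## Synthetic cohort generator

The generator emulates the *structure* of a pulmonary-function report
database, not lung physiology. Per class it draws measurements from
truncated normals whose supports are placed relative to the decision
thresholds:

- **healthy:** all indices inside reference limits with margin
  (R5 ≈ 95 %pred, deficit ≈ 0.04, ratio ≈ 0.85), no symptoms;
- **asthma (specific):** all four static criteria met with margin
  (R5 ≈ 180 %pred, deficit ≈ 0.30, ratio ≈ 0.72), asthma symptoms;
- **COPD (specific):** peripheral-obstruction picture (R5 ≈ 190 %pred,
  ΔR ≈ 0.43, deficit ≈ 0.40, ratio ≈ 0.58), history with exposure;
- **nonspecific** diseased cases (defaults: 21/170 of asthma, 36/248 of
  COPD, matching the stepwise resolution profile of the validation
  study this emulates) are drawn *near-threshold* by construction —
  failing the static gates — and carry a BDT series whose response
  magnitudes produce the correct challenge outcome. Within nonspecific
  asthma, 4/21 are BDT non-responders carrying a positive methacholine
  series (standard doses 0.0625–16 mg/mL); nonspecific COPD carries a
  non-responding BDT and resolves through the fixed-ratio gate.

Ages follow the validation cohort profile (asthma 19.85 ± 8.185, COPD
52.25 ± 7.636, healthy 30.03 ± 11.833 years), truncated *symmetrically*
about the mean so truncation does not bias it; the COPD lower bound of
41 guarantees the age criterion. Smoking and allergy prevalences follow
the same cohort's per-class rates. Default class counts are 170/248/37
(the validation cohort) and the training configuration used by the
acceptance script is 437/438/125, which under the 80/20 split yields a
350/350/100 estimation set.

`noise_scale` (default 0; the CLI default is 0.05 for training-grade
realism) applies multiplicative Gaussian noise to every stored
measurement after construction, with floors keeping values physiologic
and FEV1/FVC ≤ 1.2. At noise 0 label recovery through the workflow is
100 % by construction — this is a *consistency* guarantee between
generator and classifier, not evidence about real patients. What
passing tests show: the rules, challenge logic and training machinery
are implemented coherently. What they do not show: performance on real
measurement distributions, which overlap class boundaries, correlate
spirometry with IOS abnormality, and contain ambiguous symptom
histories. No covariance between spirometry and IOS abnormality is
modelled beyond their threshold co-occurrence, and no mechanistic
(equivalent electrical) lung model is involved.

One shared seeded stream draws everything in a fixed, documented order
(age, smoking, allergies, nonspecific flag, BPT-bound flag, the ten
baseline measurements, challenge magnitudes, noise), so adding a
parameter never silently reorders existing draws.

## Metrics

The 3×3 confusion matrix (true × predicted over asthma/COPD/healthy)
collapses to diseased-vs-healthy with disease cross-confusions counted
as test-positive — the only collapse consistent with treating "test
outcome positive" as "called diseased". Two sensitivities are reported:
`tpr` (diseased called diseased) and `disease_sensitivity` (diseased
given the *correct* disease label). All metrics are kept at full
precision internally; the conventional half-up 2-decimal rounding is a
formatting step, because rounding both members of a complementary pair
can otherwise sum to 100.01 (e.g. 99.875/0.125). Zero denominators
yield an explicit undefined marker (`None`), never an exception.
Prevalence is always computed from the counts themselves
(418/455 → 91.87 %); a source table printing a different prevalence for
the same counts is treated as a typographical slip.

## Problem sizes and defaults used in verification

The test suite and acceptance script use the cohort sizes the emulated
study reports: a 455-report (170/248/37) noise-free validation run and
a 1000-report (437/438/125, noise 0.05) training run with an 800/200
split and 10 hidden units. Both complete in seconds on one CPU; LM
typically converges to the SSE tolerance in ~20 iterations on the
training run because the symptom flags make the classes nearly
separable.

## Known limitations

- The generator's distribution parameters are structural defaults, not
  epidemiological estimates; only threshold relationships are calibrated.
- The fuzzy pattern feeds the feature vector and the healthy check, but
  the static disease criteria are crisp; a patient straddling a
  breakpoint is resolved by the challenge cascade, not by partial
  degrees.
- GOLD A–D subgrouping, severity staging, PC20 interpolation, and
  ROC/AUC analysis are out of scope.
- CSV cohorts hold the baseline plus a single post-BDT step; multi-dose
  BPT series require the JSON format.
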