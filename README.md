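# anfiskit

Adaptive neuro-fuzzy (ANFIS) screening models for early detection of
developmental disabilities in young children, with a seeded synthetic-cohort
simulator, transparent evaluation machinery and interpretable clinical
reporting.

## The problem

Developmental disabilities affect roughly one child in six, yet diagnosis is
slow and unevenly accessible. Screening classifiers built on standard
multi-domain assessments (cognitive, behavioral, motor and social-interaction
scores on a 0–100 scale, plus age, sex and family history) can help triage,
but black-box models are hard to justify clinically. A Sugeno-type Adaptive
Neuro-Fuzzy Inference System offers a middle road: it learns like a neural
network but expresses its knowledge as fuzzy if–then rules over linguistic
categories (Low / Medium / High) that clinicians can inspect.

`anfiskit` implements that analysis end to end for researchers and
methodologists: simulate a realistic cohort, engineer the model inputs, train
and evaluate the classifier, and turn predictions into clinician-facing
reports with confidence tiers.

## The model

Each normalised input $x_f \in [0,1]$ is fuzzified by three Gaussian
membership functions $\mu_{f,m}(x_f) = \exp\!\big(-(x_f - c_{f,m})^2 / 2\sigma_{f,m}^2\big)$
with learnable centers and widths. Rule $k$ selects one membership function
per feature; its firing strength is the product T-norm
$w_k = \prod_f \mu_{f,a_{k,f}}(x_f)$, computed in log space with an underflow
floor. Normalised strengths $\bar w_k = w_k / \sum_j w_j$ weight first-order
Sugeno consequents, and a sigmoid maps the aggregate to a probability:

$$\hat p = \sigma\Big(\textstyle\sum_{k=1}^{8} \bar w_k\,(p_k^\top x + r_k)\Big).$$

The default architecture is 11 features × 3 membership functions with 8
rules. All parameters are trained jointly by Adam (learning rate 0.01, batch
size 32, up to 100 epochs, early stopping with patience 10 on a 20%
validation split) minimising binary cross-entropy, with hand-derived analytic
gradients.

The 11 engineered features are the four raw domain scores, four
age-adjusted ratios (score / age), two cross-domain ratios —
cognitive/(social+1) and motor/(behavioral+1) — and a weighted composite risk
$\big(0.3(100-C) + 0.2(100-B) + 0.2(100-M) + 0.3(100-S)\big)\cdot m_{\text{FH}}$
with a multiplicative family-history factor.

## Worked example

```python
import numpy as np
from anfiskit import cohort, pipeline, report

records = cohort.generate_cohort(cohort.CohortConfig(seed=0))  # 4311 + 689 children
results, data = pipeline.fit(records)                          # 80/20 stratified split
print(results.summary())
metrics = results.evaluate(data.X_test, data.y_test)
print(f"test AUC {metrics.auc:.3f}, accuracy {metrics.accuracy:.3f}")
```

prints (abridged):

```
ANFIS classifier results
============================================================
features: 11   membership functions/feature: 3
rules: 8   consequent order: linear (first-order Sugeno)
n obs: 4000   positives: 551 (13.8%)
epochs run: 86   best epoch: 75
best validation loss: 0.2480   validation accuracy: 0.9087
...
test AUC 0.870, accuracy 0.889
```

The AUC of 0.87 is what the synthetic cohort's group separation supports:
four domains with standardised mean differences of 0.6–0.8 plus the
family-history signal. Turning one child into a clinical report:

```python
case = {"child_id": "demo", "age": 4, "sex": "female",
        "cognitive_score": 64.45, "behavioral_score": 74.14,
        "motor_skills": 68.35, "social_interaction": 61.20,
        "family_history": 0, "diagnosis": 0}
print(report.generate_report(case, results).to_text())
```

```
Clinical screening report — child demo
========================================================
Prediction       : no diagnosis
Probability      : 0.000
Confidence       : 99.9% (High)

Domain assessment (membership classification):
  cognitive_score        64.45  Medium
  behavioral_score       74.14  High
  motor_skills           68.35  Medium–High
  social_interaction     61.20  Medium

  cognitive_social_ratio 1.04   composite_risk 33.81
...
Recommendation: Continue routine monitoring
```

The same pipeline is scriptable from a shell:

```bash
anfiskit simulate --out out           # cohort.csv + cohort_summary.csv
anfiskit train --cohort out/cohort.csv --out out
anfiskit evaluate --cohort out/cohort.csv --model out/model.json --out out
anfiskit crossval --cohort out/cohort.csv --out out
anfiskit importance --cohort out/cohort.csv --model out/model.json --out out
anfiskit report --model out/model.json --cognitive 64.45 --behavioral 74.14 \
    --motor 68.35 --social 61.20 --age 4
```

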