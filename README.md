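# shortform

Build short versions of questionnaire measures that still recover the
scores of the full-length measure.

Long self-report scales burden participants, degrade data quality and cost
money. `shortform` derives a brief, re-weighted item subset whose weighted
sum accurately predicts the scores a participant *would* have obtained on
the complete measure — total sum scores, subscale sums, or factor scores
from an exploratory factor analysis. It is aimed at researchers in
psychology, psychiatry and adjacent fields who need to shorten a validated
measure (or a battery of measures) without building item-response-theory
models, and it works for multidimensional scales where IRT-based shortening
does not apply.

## Method

Observed scores *y* are modelled as a linear weighted sum of item
responses,

  ŷ = w₁x₁ + w₂x₂ + ⋯ + b,

and items are dropped by driving their weights to exactly zero with
L1-regularized (Lasso) regression, whose penalty strength α controls how
brief the short form is. For multidimensional targets no single α suits
every dimension, so a two-step procedure is used:

1. **Select** — fit one Lasso per target dimension (its own α), giving a
   retained item set per dimension.
2. **Re-weight** — take the union of retained items and refit plain
   least-squares models predicting every dimension from that shared set.

Because there is no single "correct" α, a randomized search draws candidate
per-dimension strengths from a scaled Beta(1, 3) distribution (1000
iterations by default), evaluates each candidate on a validation split, and
exposes the whole brevity/accuracy frontier. A scalar score,

  score = min(R²) · (1 − n_included / n_total),

balances accuracy (worst-dimension validation R²) against length; final
accuracy is reported on a held-out test split. A synthetic Likert-response
generator with a known two-correlated-factor structure (`sticsa_like`: 22
items, two factors of 11, four response categories) makes the whole
pipeline runnable and testable with no external data.

## Worked example

```python
from shortform import (best_model, evaluate, frontier_curve, generate,
                       make_preset, run_search, split, sum_scores)
from shortform.targets import TargetScores

spec = make_preset("sticsa_like")
data = generate(spec, seed=42, n=1622)
targets = sum_scores(data.responses)

parts = split(1622, (0.6, 0.2, 0.2), seed=42)   # -> sizes (972, 325, 325)
subset = lambda idx: (data.responses.iloc[idx].reset_index(drop=True),
                      TargetScores(targets.values.iloc[idx].reset_index(drop=True), "sum"))
(train_X, train_y), (val_X, val_y), (test_X, test_y) = map(
    subset, (parts.train_idx, parts.validation_idx, parts.test_idx))

frontier = run_search(train_X, train_y, val_X, val_y,
                      n_iterations=1000, scale=8.0, seed=42)
print(frontier_curve(frontier))
```

The frontier table shows the best validation R² at each length; this run
evaluated 273 candidate models (draws that regularized every item away are
dropped) and its low end reads:

```
 n_included   min_r2
          3 0.890846
          4 0.928932
          5 0.943510
          6 0.952974
          7 0.957134
          8 0.963944
          9 0.968423
         10 0.973606
```

So a 9-item short form — 13 of 22 items dropped — already explains ~97% of
the variance in full-scale sum scores on validation data. Confirming on the
test split:

```python
nine = max((r for r in frontier.records if r.n_included <= 9),
           key=lambda r: r.r2_validation.min())
print(evaluate(nine.model, test_X, test_y)["r2"])   # total: 0.975
```

`best_model(frontier)` instead maximizes the brevity/accuracy score and
here picks a 2-item model (score 0.783, test R² 0.891) — deliberately
aggressive; most users will choose a length from the frontier themselves.
Fitted weights export to a plain CSV (one row per retained item plus an
intercept row) so scores can be computed in a spreadsheet with no code.

The same workflow is available from the shell:

```bash
shortform simulate --preset sticsa_like --n 1622 --seed 42 --out resp.csv
shortform fit --responses resp.csv --mode sum --iterations 1000 --seed 42 \
          --model-out model.json --weights-out weights.csv
shortform predict --weights weights.csv --responses resp.csv --out scores.csv
```

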