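# fourfold

A toolkit for 2×2 binary contingency structures — the fourfold tables
behind diagnostic testing, binary classification, epidemiological risk,
and the classic Bayesian reasoning puzzles.

The same four joint counts

|          | C  | ¬C  |
|----------|----|-----|
| **T**    | a  | b   |
| **¬T**   | c  | d   |

underlie sensitivity and specificity, precision and recall, likelihood
and odds ratios, χ² and the Matthews correlation, absolute and relative
risk. Every such measure is a *focus* on the table: a ratio of cell sums,
optionally after conditionalizing by row (`a/(a+b)` is the PPV), by
column (`a/(a+c)` is the sensitivity), or by diagonal (`(a+d)/N` is the
accuracy). `fourfold` makes those perspective operations first-class:
every computed value carries the full chain of its derivation
(filter → frame → focus) plus a cell-role icon, so a report can state
*how* a number was obtained and what information the derivation dropped.

The package is aimed at methodologists, instructors of risk literacy and
evidence-based medicine, and anyone who needs the cross-domain metric
zoo in one place with consistent, inspectable definitions.

## What's inside

- **tables** — frequency, probability, and conditional 2×2 tables; the
  eight spatial layouts of one table; exact inverse transformations
  (denormalize, reconstruct-from-conditionals) when the dropped margins
  are resupplied; partially known tables with eager consistency checks.
- **grid** — cross-classification of record sets into 2^d grids; the
  partial cube {X, Y, Z = correspondence(X, Y)} whose three matrix and
  six tree projections are all informationally equivalent (and whose
  spatial arrangements number 24 at every level).
- **metrics** — the full catalog with domain aliases
  (sensitivity ≅ recall, PPV ≅ precision, relative risk shares its
  formula with LR+), undefined-value markers instead of silent NaNs, and
  a machine-readable JSON export.
- **problems** — the mammography problem in three formats, the cab
  problem, Monty Hall (exact case enumeration, arbitrary host bias), and
  the Titanic rescue-policy analysis, plus the predicted wrong answers
  (false inputs / false measure / false framing).
- **render** — deterministic text matrices, frequency trees, metric
  icons, and transparency reports whose recorded steps replay to the
  reported value.
- **io / cli** — CSV record files, a seeded synthetic record generator,
  and the `fourfold` command-line tool.

## Worked example

The screening-test problem: prevalence 1%, sensitivity 80%, false
positive rate 9.6%. For 1 000 women this reconstructs the table
(a, b, c, d) = (8, 95, 2, 895):

```
$ fourfold solve mammography:standard
PPV = 7.8%

$ fourfold metrics --builtin mammography --names accuracy,PPV,DOR
accuracy = 90.3%
PPV = 7.8%
DOR = 37.684
```

The test is highly accurate (90.3% of cases fall on the agreement
diagonal) and strongly discriminating (diagnostic odds ratio ≈ 37.7),
yet a woman with a positive result has only a 7.8% probability of
actually having the condition — the predictive value conditionalizes on
the 103 positive tests, not on the 10 true cases. The tree view makes
the solution-relevant split explicit:

```
$ fourfold render --builtin mammography --as tree --first-branch test
root: 1000
├─ test=T: 103
│  ├─ condition=C: 8
│  └─ condition=nC: 95
└─ test=nT: 897
   ├─ condition=C: 2
   └─ condition=nC: 895
```

The cab problem (prior 0.15, witness accuracy 0.80) with its predicted
reasoning errors:

```
$ fourfold solve cab --errors
PPV = 41%
  E1_false_inputs: 80% — right formula, wrong inputs: a/(a+b) computed on the by-column conditional cells (base-rate neglect)
  E2_false_measure: 80% — the inverse conditional p(T|C) reported as the answer (inverse fallacy)
```

Both wrong routes land on the witness accuracy of 80%, which is why the
intuitive-but-wrong answer is so compelling; the correct posterior is
41%.

From Python:

```python
import fourfold as ff

t = ff.from_probability_format(0.01, 0.80, 0.096, 1000)
ppv = ff.compute(t, "PPV")
report = ff.transparency_report(ppv)
print(report.value_formatted)        # 7.8%
print(report.lost_information)
# ('population size N dropped at normalization',
#  'prevalence and bias margins dropped at by_row conditionalization')
```

## Documentation

`docs/methods.md` describes the model, the conventions (canonical
orientation, rounding, undefined-value policy), the synthetic-data
generator, and known limitations.
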