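# skinsens

Two-stage machine-learning "defined approach" for predicting human skin
sensitization from in vitro assays, physicochemical descriptors and a
SMILES-language-model feature.

## The problem

Allergic contact dermatitis is driven by chemicals that sensitize the skin.
Regulators need non-animal methods that combine in vitro assay readouts —
DPRA peptide depletion (C- and K-peptide, %), the KeratinoSens EC1.5
concentration (right-censored at 2000), the binary h-CLAT call and the
5-level SENS-IS class — with computed molecular descriptors to predict both
the *hazard* (sensitizer vs non-sensitizer) and the *potency* (strong 1A vs
weak 1B) of a substance, relative to 6-level human-evidence categories
(1–4 sensitizers, 5–6 non-sensitizers).

## The model

Each stage is a **bagging ensemble of five XGBoost classifiers**: five
bootstrap subsets (80% of the training set, drawn with replacement) each get
an exhaustive hyperparameter grid search (learning rate, boosting rounds,
depth, subsample, `scale_pos_weight`) scored by 5-fold cross-validated
balanced accuracy; the stage's call is the majority vote of the five hard
labels. The two stages cascade: stage 1 separates sensitizers from
non-sensitizers; stage 2, trained on true sensitizers only, separates
1A from 1B. Binary stages are scored by

    accuracy = (TP+TN)/(TP+TN+FP+FN)        sensitivity = TP/(TP+FN)
    specificity = TN/(FP+TN)                F1 = 2TP/(2TP+FP+FN)
    balanced accuracy = (sensitivity+specificity)/2

plus two ROC-AUC readings (hard-label and vote-fraction based). Feature
selection uses gain importance averaged over the five learners (top-k with
tie inclusion, optional assay substitution), and per-substance explanations
are exact TreeSHAP attributions averaged over the ensemble. A synthetic-data
generator emulates the statistical structure of a Cosmetics-Europe-style
battery (imbalanced 6-category labels, potency-monotone assays, censored
EC1.5, correlated descriptor blocks) with a tunable effect size, so the
whole pipeline is testable offline.

## Worked example

```python
import skinsens as sk

dataset = sk.generate(n=122, effect=2.0, seed=17)        # synthetic battery
result = sk.run_study(dataset, seed=17,
                      stage1_grid=sk.MINIMAL_GRID, stage2_grid=sk.MINIMAL_GRID)
print(len(result.split.train_ids), len(result.split.test_ids))
print(round(result.stage1_metrics["balanced_accuracy"], 4))
print(result.potency_report["overall_pct"])
```

prints

```
97 25
1.0
96.0
```

i.e. the 122 substances split 97 train / 25 test stratified by potency
category; the hazard stage separates this strongly-informative synthetic
battery perfectly (held-out balanced accuracy 1.0); and 96% of the 25 test
substances get the correct NC/1B/1A call from the cascaded model (at
`effect=2.0` the generated assays are nearly noise-free — real batteries sit
well below this).

The same pipeline is scriptable from a shell:

```bash
skinsens simulate --out table.csv --n 122 --effect 2 --seed 17
skinsens train --data table.csv --out run/ --seed 17 --grid minimal
skinsens predict --model run/model --data table.csv --out pred.csv
skinsens evaluate --predictions pred.csv --labels table.csv --out report.json
skinsens explain --model run/model --data table.csv --out shap/
```

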