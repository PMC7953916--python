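# regenscore

Practice-based scoring of regenerative farm operations, with the
statistics used to validate such scores against measured outcomes.

Certifiers, researchers and producers need a transparent way to call an
operation "regenerative" without auditing every outcome on every farm.
`regenscore` implements a composite practice score for cropland and
rangeland, a natural-break classifier that splits scored operations into
regenerative and conventional clusters, the soil and biodiversity
response metrics those scores are validated against, and the regression
machinery for the validation itself — plus a synthetic farm-data
generator so the entire pipeline can be exercised and calibrated without
any field data.

## The score

Cropland operations answer nine binary practice questions. Eliminating a
uniform disturbance is regenerative (coded 1): no synthetic fertilizers,
no herbicides, no fungicides, no insecticides, no tillage. Adding
diversity is regenerative (coded 1): cover crops or deliberately
fostered resident vegetation, diversified field margins/hedgerows,
organic amendments, livestock integration. The composite score is the
unweighted sum, `S = Σ x_i`, with maximum 9 (or 6 where only six items
are asked, as in corn surveys that omit fungicides, margins and
amendments).

Rangeland operations answer four ordinal questions coded 0–2 (maximum 8):

| item | 0 | 1 | 2 |
|---|---|---|---|
| ivermectin use | multiple/yr or during grazing | single, off-season | none |
| stocking density (AU/ha) | < 5 | 5–10 | > 10 |
| rotation frequency (days) | ≥ 30 | 10–30 | < 10 |
| rest period (days) | 0 (continuous) | 1–30 | > 30 |

Observed scores are strongly bimodal: operations cluster near 0 or near
the maximum. `GapThresholdClassifier` finds the widest gap between
consecutive distinct scores and divides at the rounded midpoint — on the
packaged rangeland matrix the dividing score is 3, on the almond-orchard
matrix it is 5.

Validation regresses outcomes (soil carbon stocks at equivalent soil
mass, organic matter by loss-on-ignition, Haney soil-health scores,
infiltration rates, invertebrate diversity, yield, net profit) on the
score: OLS on operation-composited values with soil clay % as a
co-factor where relevant, linear mixed models (REML) with farm/field
random intercepts and month fixed effects where operations were
resampled, and a CV-versus-score trend testing whether performance
variability grows with the score.

## Worked example

```python
from regenscore import (RangelandProfile, composite_score,
                        GapThresholdClassifier)
from regenscore.datasets import rangeland_scores

ranch = RangelandProfile(
    operation_id="demo-ranch",
    ivermectin_applications_per_year=0,
    ivermectin_applied_during_grazing=False,
    stocking_density_au_per_ha=12.0,    # high-density AMP grazing
    rotation_frequency_days=3.0,        # moved every few days
    rest_period_days=60.0,              # long recovery
)
rec = composite_score(ranch)
print(rec.item_codes)
print(rec.composite_score, "/", rec.max_possible)

clf = GapThresholdClassifier().fit(rangeland_scores())
print(clf.dividing_score_, clf.predict([rec.composite_score])[0])
```

prints

```
{'ivermectin': 2, 'stocking_density': 2, 'rotation_frequency': 2, 'rest_period': 2}
8 / 8
3 regenerative
```

The ranch codes 2 on every item (no ivermectin, > 10 AU/ha, < 10-day
rotations, > 30-day rest), scoring the rangeland maximum of 8. Fitting
the threshold on the 52 packaged ranch scores puts the dividing score at
3 (the widest gap in observed scores lies between 2 and 4), so the demo
ranch is classified regenerative.

The same pipeline runs from the shell:

```
regenscore score survey.csv --out scores.csv
regenscore classify scores.csv            # threshold.json + labels.csv
regenscore --seed 42 simulate             # synthetic bundle
regenscore validate outcomes.csv --models models.yaml
```

## Layout

| module | contents |
|---|---|
| `regenscore.rubric` | item coders, `composite_score`, `RegenerativeScorer` |
| `regenscore.classify` | `find_threshold`, `GapThresholdClassifier` |
| `regenscore.soil` | LOI, fPOM, bulk density, infiltration, Haney, ESM stocks |
| `regenscore.community` | Shannon H, Gini–Simpson, richness, guilds, vegetation |
| `regenscore.validation` | OLS / mixed-model / CV-trend fits, `run_validation` |
| `regenscore.simulate` | synthetic profiles, outcomes, communities, soil profiles |
| `regenscore.io` | survey I/O, net profit ledger, report assembly |
| `regenscore.datasets` | packaged cropland/rangeland practice matrices |
| `regenscore.cli` | `regenscore` command |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
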