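# kanokit

Kano-model analysis of paired functional/dysfunctional survey
questionnaires, for researchers who classify user or patient needs from
Likert-scale surveys: health-services and nursing researchers, UX and
service-design analysts, and anyone running a "better/worse coefficient"
study.

## The method

A Kano survey asks, for every candidate feature, a *functional*
question ("If this feature were available, how would you feel?") and a
*dysfunctional* one ("If it were NOT available?"), each on a 5-point
scale (1 = I like it that way … 5 = I dislike it that way).  The answer
pair indexes the standard 5×5 evaluation table, yielding one of six
categories per respondent: must-be (M), one-dimensional (O), attractive
(A), indifferent (I), reverse (R) or questionable (Q).  Each item's
final attribute is its modal category.

From the per-item counts the two coefficients are

    SI  =  (A + O) / (A + O + M + I)        ∈ [0, 1]   "better"
    DSI = −(O + M) / (A + O + M + I)        ∈ [−1, 0]  "worse"

Items are plotted at (|DSI|, SI); splitting the plane at the per-axis
means gives four strategy quadrants: **I predominance** (high
importance, high satisfaction), **II improving**, **III secondary
improving**, **IV reserving**.  Ties on a boundary go to the
high-importance / high-satisfaction side.

The package also covers the surrounding survey workflow: respondent
screening (logic-error flags, minimum completion time) with
response-rate accounting, Kendall-rule sample-size planning (5–10× the
variable count, inflated for non-response), Cronbach's α and Cohen's κ
reliability statistics, and a seed-reproducible synthetic-respondent
generator for testing pipelines without raw data.

## Worked example

The bundled dataset is the aggregated frequency table of a published
cross-sectional survey in which 1,571 hospital nurses rated 26 candidate
features of a digital mental-health support tool.

```python
import kanokit as kk

rows = kk.load_nurse_demand()          # 26 items × 1,571 respondents
report = kk.run_pipeline(rows)

print({c.tag: v for c, v in report.attribute_tally.items()})
print(f"origin = ({report.origin.x0:.2f}, {report.origin.y0:.2f})")
for q, ids in report.quadrant_membership.items():
    print(q.name, q.strategy_name, ids)
```

prints

```
{'A': 7, 'O': 8, 'M': 8, 'I': 3}
origin = (0.43, 0.49)
I predominance ['2', '3', '4', '11', '15', '16', '19', '20']
II improving ['1', '9', '12', '13', '14', '24', '26']
III secondary improving ['17', '22', '23']
IV reserving ['5', '6', '7', '8', '10', '18', '21', '25']
```

i.e. 8 must-be, 8 one-dimensional, 7 attractive and 3 indifferent
attributes; the matrix origin is the mean (|DSI|, SI) over the 26 items;
and the eight items of quadrant I (courses, counseling, testing, games,
music, white noise, privacy, confession) are the ones whose absence
would cost the most satisfaction while their presence delivers the most.

The same pipeline runs from a shell:

```sh
kano analyze --input survey.csv --codebook codebook.yaml --min-seconds 180 --out results/
kano simulate --spec sim.yaml --out synthetic.csv --seed 42
kano plan --k 26 --inflation 1.2
```

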