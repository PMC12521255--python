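# padcare

Emotional experience evaluation for smart older-adult care service systems,
built on the pleasure–arousal–dominance (PAD) dimensional emotion model.

Community smart-care systems are commonly decomposed into three structural
parts — smart devices, online software and offline services — evaluated
through 18 clustered service touchpoints ("indicators", `S_1`…`S_18`).
`padcare` implements the full quantitative evaluation pipeline for such a
system:

1. **PAD scoring.** Each indicator is rated on 12 bipolar semantic-differential
   items (`C1`…`C12`), scored on a nine-point grid from −4 to +4. Four items
   load on each dimension, half reverse-oriented, and the dimension score is
   the signed item mean:

   ```
   P = (C1 − C4 + C7 − C10) / 4
   A = (−C2 + C5 − C8 + C11) / 4
   D = (C3 − C6 + C9 − C12) / 4
   ```

2. **Emotion tendency.** The measured point (P, A, D) is compared with 8
   benchmark emotions with normative PAD coordinates (Joy, Relaxation,
   Surprise, Reliance — positive polarity; Boredom, Fear, Anxiety, Anger —
   negative) by Euclidean proximity
   `L = √((P−P_N)² + (A−A_N)² + (D−D_N)²)`; the nearest benchmark is the
   indicator's emotional tendency.

3. **Demand assessment.** From single-score "initial questionnaire" ratings,
   each indicator's mean `m_i` and SD `s_i` are compared with its part's
   pooled benchmark `(m_b, s_b)`: `s_i < s_b` with `m_i > m_b` ⇒ *positive*
   demand; `s_i < s_b` with `m_i ≤ m_b` ⇒ *unactivated*; `s_i ≥ s_b` ⇒
   *potential* (dispersed, conflicted responses, regardless of the mean).

4. **Synthetic cohorts.** A seeded respondent simulator generates item-level
   and demand-score cohorts whose aggregates target given PAD points and
   mean/SD moments, enabling parameter-recovery studies without raw survey
   data.

The aggregate inputs of a published evaluation of a Chinese community smart
care system (item-mean matrix, benchmark coordinates, demand statistics)
ship with the package as CSV data and are the defaults throughout.

## Worked example

```python
import padcare as pc

codebook = pc.default_codebook()
benchmarks = pc.default_benchmarks()
results = pc.evaluate_all(pc.published_item_means(), codebook, benchmarks)
print(results[["indicator_code", "P", "A", "D", "tendency"]].head(3).round(4))

table, summary = pc.assess_from_stats(pc.published_demand_stats(), codebook)
print(summary["counts"], summary["percentages"])
```

prints

```
  indicator_code       P       A     D    tendency
0            S_1  2.7050  1.6000  1.36         Joy
1            S_2  1.9200 -0.6425  1.00  Relaxation
2            S_3 -0.4500  0.4650 -0.5225  Anxiety
```

— wearable health devices (`S_1`) sit nearest the Joy benchmark
(proximity 0.3999), while self-service check-up devices (`S_3`) land nearest
Anxiety; in total 10 of 18 indicators lean toward a positive emotion — and

```
{'positive': 10, 'unactivated': 5, 'potential': 3}
{'positive': 55.6, 'unactivated': 27.8, 'potential': 16.7}
```

— the demand rule classifies 10 indicators as positive, 5 as unactivated and
3 as potential demands (percentages half-up to 1 decimal over 18).

The `examples/` directory contains one short narrative script per
capability (`score_indicators.py`, `demand_assessment.py`,
`simulate_recovery.py`, `system_report.py`), and the `padcare` command
exposes the same stages on CSV files (`padcare score|demand|simulate|report
--help`).

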