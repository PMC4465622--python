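"""Ordinal ossification scoring: frequency tables and the weighted global score.

Generates a PTH-like cohort (treatment suppresses ossification), pools the
bilateral structures, tabulates category frequencies and compares the
per-larva global scores (weights 0/1/2/4 for absent/early/advanced/over).
"""

from osteomorph import (
    compare_global_scores,
    frequency_table,
    global_scores,
    pool_bilateral,
)
from osteomorph.synthetic import gen_ossification, preset_scenarios

scenario = preset_scenarios()["pth_like"]
records = gen_ossification(scenario.ossification, scenario.config(n=27, seed=42))

freq = frequency_table(pool_bilateral(records))
angulo = freq[freq["structure"] == "anguloarticular"]
print("anguloarticular category frequencies (%):")
print(angulo.pivot_table(index="condition", columns="category", values="pct").to_string())

scores = global_scores(records)
result = compare_global_scores(scores)
print("\nglobal ossification score (sum of 0/1/2/4 weights over 16 elements):")
for cond, s in result["conditions"].items():
    print(f"  {cond}: {s['formatted']}  (n={s['n']})")
print(f"  {result['test']}: p = {result['p']:.3g} {result['stars']}")
print(
    "\nThe treated mean is about half the control mean — the generated"
    " cohorts emulate a strong suppression of bone formation."
)
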