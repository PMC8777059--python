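"""Label self-assessments under both schemes and summarize a cohort.

The pleasure/stress (PS) rule is the binary scheme the classifiers are
trained on: positive iff pleasure > 0 and stress <= 1, negative iff
pleasure < 0 or stress > 2, otherwise excluded.  The valence-arousal
quadrant mapping is shown for comparison.
"""

from rteeg.labeling import Ratings, label_ps, summarize_labels, va_quadrant
from rteeg.synthetic import GeneratorConfig, generate_cohort

for p, a, s in [(3, 2, 1), (1, 0, 5), (2, 1, 2), (-4, -1, 6)]:
    r = Ratings(p, a, s)
    print(f"P={p:+d} A={a:+d} S={s}: PS -> {label_ps(r).value:8s} "
          f"VA -> {va_quadrant(p, a).value}")

# A full-size stratified cohort reproduces the study composition exactly.
cohort = generate_cohort(GeneratorConfig(duration=1.0, stratified=True, seed=0))
summary = summarize_labels(cohort.ratings_table().ratings())
print(f"\n{summary.n_rows} trials:")
for label, count in summary.ps_counts.items():
    print(f"  {label.value:8s} {count}")
# Expect 126 positive / 69 negative / 201 excluded: only the 195
# positive+negative trials reach the classifiers.
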