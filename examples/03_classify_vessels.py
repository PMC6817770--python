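"""Classify measured vessels and compare the two decision criteria.

Generates the full default study (81 venule-like + 31 arteriole-like
vessels), classifies every vessel with both criteria, and shows why the
area-ratio rule is preferred: it assigns every vessel, while the
diameter-ratio rule can only call the unambiguous large-ratio venules.
"""

import warnings

from vesselmorph import (
    PopulationSpec,
    classify_area_ratio,
    classify_diameter_ratio,
    measure,
    range_overlap,
    sample_population,
)

pairs = sample_population(PopulationSpec(master_seed=1))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    records = [(measure(v), t) for v, t in pairs]

area_calls = {"venule": 0, "arteriole": 0, "indeterminate": 0}
diam_calls = {"venule": 0, "arteriole": 0, "indeterminate": 0}
correct = 0
for rec, truth in records:
    a = classify_area_ratio(rec)
    d = classify_diameter_ratio(rec)
    area_calls[a.assigned_class] += 1
    diam_calls[d.assigned_class] += 1
    expected = "venule" if truth.spec.group_label == "venule_like" else "arteriole"
    correct += a.assigned_class == expected

print(f"area-ratio rule:     {area_calls}  ({correct}/112 match the true group)")
print(f"diameter-ratio rule: {diam_calls}")

a1 = [r.area_ratio for r, t in records if t.spec.group_label == "venule_like"]
a2 = [r.area_ratio for r, t in records if t.spec.group_label == "arteriole_like"]
overlaps, interval = range_overlap(a1, a2)
print(f"\nmeasured area-ratio ranges: venule-like [{min(a1):.2f}, {max(a1):.2f}], "
      f"arteriole-like [{min(a2):.2f}, {max(a2):.2f}] -> overlap: {overlaps}")
print("The empirical gap (1.57, 1.89) maps to an explicit 'indeterminate'")
print("class; with supports inside the published ranges nothing lands there.")
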