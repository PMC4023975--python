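"""Class-mean profiles and negative-class outlier flagging.

The per-parameter class means of the selected markers show the signature
geometry: the "increased" class sits between negative and positive.
Negative animals that deviate strongly on several top markers at once are
flagged as candidates for histopathology re-evaluation.
"""

import hepamark as hm

study, _ = hm.generate_study(hm.default_config(seed=1))
deltas = hm.center_study(study)
classes = hm.classify_study(study, deltas["clinical_chemistry"])

ranked = hm.rank_markers(
    hm.discover_markers(deltas["transcripts_liver"], classes)
)
selected = [r.parameter_id for r in ranked if r.significant]

profile = hm.class_profile(deltas["transcripts_liver"], classes, selected)
print("mean of per-marker class means (log2 scale):")
print(profile.means.mean().round(2).to_string())
# negative ~ 0 < increased < positive: the intermediate position of the
# increased class supports treating it as early, pre-morphological injury.

top = [r.parameter_id for r in ranked[:5]]
flags = hm.flag_outliers(deltas["transcripts_liver"], classes, top,
                         k_markers=3, fold_threshold=2.0)
print(f"\nnegative-class animals deviating on >=3 of the top 5 markers: "
      f"{len(flags)}")
for f in flags:
    trig = ", ".join(f"{m} {fc:.1f}x" for m, fc in f.triggers)
    print(f"  {f.sample_id}: {trig}")
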