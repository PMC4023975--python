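"""Phenotype-anchored classification and ALT/AST rule diagnostics.

Each animal becomes negative / increased / positive: any qualifying
histopathology finding forces positive; otherwise a >= 2-fold rise in ALT
or AST over the time-matched vehicle mean gives "increased".  The enzyme
rule is then scored as a diagnostic against the histopathology anchor.
"""

import hepamark as hm

study, _ = hm.generate_study(hm.default_config(seed=1))
deltas = hm.center_study(study)
classes = hm.classify_study(study, deltas["clinical_chemistry"])

tally = hm.class_tally_by_treatment(study, classes)
print("per-treatment class tallies:")
print(tally.to_string())

outcomes = hm.alt_ast_rule_outcomes(study, deltas["clinical_chemistry"])
counts = hm.rule_confusion(classes["class"].tolist(),
                           outcomes.loc[classes.index].tolist())
sens, spec = hm.sens_spec(counts)
print(f"\nALT/AST rule vs histopathology: tp={counts.tp} fn={counts.fn} "
      f"fp={counts.fp} tn={counts.tn}")
print(f"sensitivity {sens:.0%}, specificity {spec:.0%}")
# Sensitivity is how many histopathology-positive animals the serum enzymes
# alone would have caught; the false positives are exactly the "increased"
# class - possible early injury without morphological correlate.
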