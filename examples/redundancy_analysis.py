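"""Find redundant DSM-5 ADHD symptom pairs from the bundled layer scores.

Fuses the three similarity layers with entropy weights and selects pairs
above the relaxed 99th-percentile cutoff, per symptom domain.
"""

import symscreen as ss

for name, domain in [("table5_inattention", "inattention"),
                     ("table6_hyperactivity", "hyperactivity/impulsivity")]:
    table = ss.load_bundled(name)
    weights, combined, threshold = ss.redundant_pairs(table)
    print(f"--- {domain} ---")
    print("layer weights:",
          {k: round(v, 2) for k, v in weights.as_dict().items()})
    print(f"99th-percentile cutoff: {threshold.cutoff:.2f} "
          f"(relaxed by {threshold.relaxation})")
    for pair in threshold.selected:
        score = combined[table.pair_labels.index(pair)]
        print(f"  redundant pair {pair}: combined similarity {score:.2f}")

# The weights say which layer carries the most information (semantic
# dominates in both domains); the selected pairs are the symptom
# statements whose wording overlaps enough to question their
# distinctiveness as separate diagnostic items.
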