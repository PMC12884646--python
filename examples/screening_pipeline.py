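"""Run the two-stage screening pipeline on a synthetic questionnaire.

Stage 1 filters ADHD-consistent items from non-ADHD behavioural language;
stage 2 assigns surviving items to the inattention (0) or hyperactivity/
impulsivity (1) domain from three similarity-difference features.
"""

import numpy as np

import symscreen as ss

dsm5 = ss.load_bundled("dsm5_adhd")
backend = ss.StubEmbedder(seed=1)

# train: 18 DSM-5 ADHD statements vs templated non-ADHD distractors
non_adhd = ss.generate_questionnaire(
    ss.SyntheticSpec(n_adhd_paraphrases=0, n_distractors=12, seed=11), dsm5
)
filter_model = ss.train_filter(dsm5, non_adhd, backend)
print("post-resampling class counts:", filter_model.resampled_counts)

# test: paraphrased ADHD items + fresh distractors, labels known
test = ss.generate_questionnaire(
    ss.SyntheticSpec(n_adhd_paraphrases=8, n_distractors=12,
                     perturbations=("synonym_swap",), seed=23),
    dsm5,
)
passed, rejected, filter_report = ss.apply_filter(filter_model, test, backend)
print(f"filter: {len(passed)} passed, {len(rejected)} rejected, "
      f"accuracy {filter_report.accuracy:.2f}, "
      f"specificity {filter_report.specificity:.2f}")

inatt = dsm5.subset("inattention")
hyper = dsm5.subset("hyperactivity_impulsivity")
X = ss.feature_matrix(dsm5, inatt, hyper, backend)
y = np.array([1 if s.domain == "hyperactivity_impulsivity" else 0 for s in dsm5])
subtype = ss.train_subtype("forest", X, y)

adhd_passed = ss.Corpus(tuple(s for s in passed if s.domain != "non_adhd"))
Xte = ss.feature_matrix(adhd_passed, inatt, hyper, backend)
truth = np.array([1 if s.domain == "hyperactivity_impulsivity" else 0
                  for s in adhd_passed])
pred = subtype.classifier.predict(Xte)
prob = subtype.classifier.predict_proba(Xte)[:, 1]
report = ss.evaluate(pred, prob, truth)
print(f"subtype (forest): accuracy {report.accuracy:.2f}, "
      f"precision {report.precision:.2f}, recall {report.recall:.2f}, "
      f"F1 {report.f1:.2f}, AUC {report.auc:.2f}")

# A high filter accuracy means the pipeline keeps ADHD-like wording and
# rejects conduct/mood language; a high subtype accuracy means the three
# similarity-difference features suffice to tell the two ADHD domains
# apart on items the model never saw verbatim.
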