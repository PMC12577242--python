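"""Train the TCR classifier on pooled training-subject TCRs and score the
validation subjects' Autoimmune Risk Scores (ARS).

The classifier never sees a validation subject's TCRs: the split is at the
individual level, and the ARS is the mean classifier probability over a
subject's representative clonotypes.
"""

from tcrars.ars import compute_ars
from tcrars.classifier import ModelConfig, TCRClassifier
from tcrars.encoding import build_vocabulary
from tcrars.repertoire_io import pool_training_tcrs, prepare_cohort, split_cohort
from tcrars.stats import auc_mann_whitney
from tcrars.synthetic import SimulationConfig, generate_cohort

cohort, _ = generate_cohort(
    SimulationConfig(n_cases=12, n_controls=12, clonotypes_per_subject=250, seed=7)
)
cohort = prepare_cohort(cohort)  # QC + top-2000 representative selection
train, val = split_cohort(cohort, 0.8, seed=0)

pool = pool_training_tcrs(train, feature_mode="cdr3+vgene")
max_len = max(len(c.junction_aa) for r in cohort for c in r.clonotypes)
vocab = build_vocabulary(pool, "cdr3+vgene", max_len=max_len)
model = TCRClassifier(ModelConfig(epochs=4, seed=1), vocab, "cdr3+vgene").fit(pool)
print(f"trained on {len(pool)} pooled TCRs from {len(train)} subjects")

records = [compute_ars(model, rep) for rep in val]
print("\nsubject        label     ARS")
for r in sorted(records, key=lambda r: -r.ars):
    print(f"{r.subject_id:<14s} {r.label:<8s} {r.ars:.3f}")
auc = auc_mann_whitney(
    [r.ars for r in records], [1 if r.label == "case" else 0 for r in records]
)
print(
    f"\nvalidation ARS AUC = {auc:.3f} "
    "(probability a random case outranks a random control; 1.0 = perfect)"
)
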