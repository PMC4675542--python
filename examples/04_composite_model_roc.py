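"""Composite logistic risk model over four binary markers, with transfer.

Recodes the three main-effect markers and the epistatic pair as 0/1 subject-
level indicators, fits a logistic model on a discovery cohort, and applies
the trained coefficients verbatim to an independent replication cohort.
"""

from epicombo import (
    CarriagePattern,
    MarkerSet,
    PatternElement,
    apply_model,
    fit_composite_logistic,
    paper_like_config,
    roc_auc,
    simulate_cohort,
)

markers = MarkerSet([
    ("TGFB1_TT", CarriagePattern.of(PatternElement("rsTGFB1", "recessive", "T"))),
    ("FGB_T", CarriagePattern.of(PatternElement("rsFGB", "dominant", "T"))),
    ("CRP_TT", CarriagePattern.of(PatternElement("rsCRP", "recessive", "T"))),
    ("IFNG_A+PTGS1_T", CarriagePattern.of(
        PatternElement("rsIFNG", "dominant", "A"),
        PatternElement("rsPTGS1", "dominant", "T"))),
])

discovery = simulate_cohort(paper_like_config(), seed=1)
replication = simulate_cohort(paper_like_config(n_case=220, n_control=197), seed=2)

model = fit_composite_logistic(discovery, markers)
print("fitted coefficients (log-OR) and Wald p:")
for name, b, p in zip(model.marker_names, model.beta, model.wald_p):
    print(f"  {name:<16} beta = {b:+.3f}   p = {p:.4f}")

scores = apply_model(model, replication, markers)
rep_auc = roc_auc(scores, replication.phenotype).auc
print(f"\ndiscovery AUC   = {model.train_auc:.3f}")
print(f"replication AUC = {rep_auc:.3f}  (trained coefficients reused, no refit)")
print("\nAUC ~ 0.66 means the four-marker score ranks a random case above a"
      "\nrandom control about two times in three - moderate discrimination.")
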