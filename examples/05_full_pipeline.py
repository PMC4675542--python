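"""End-to-end pipeline: QC, scan, mining, epistasis, model, replication.

Runs the whole analysis on a simulated discovery/replication pair and prints
a stage-by-stage summary of the structured report.
"""

from epicombo import PipelineConfig, paper_like_config, run_pipeline, simulate_cohort

discovery = simulate_cohort(paper_like_config(), seed=1)
replication = simulate_cohort(paper_like_config(n_case=220, n_control=197), seed=2)

report = run_pipeline(discovery, replication, PipelineConfig(permutations=100, seed=5))

for name, table in report.stage_tables().items():
    print(f"{name:<16} {len(table)} rows")
print()

sig = report.combinations[report.combinations["significant"]]
print(f"{len(sig)} patterns pass all gates (p_f < 0.01, p_perm < 0.05, CI excl. 1)")
if len(report.epistasis):
    print("\nSF+FLINT verdicts on surviving pairs:")
    print(report.epistasis[["factorA", "factorB", "SF", "p_flint", "call"]].to_string(index=False))
if report.model:
    print(f"\ncomposite model AUC: discovery {report.model['train_auc']:.3f}, "
          f"replication {report.model.get('replication_auc', float('nan')):.3f}")
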