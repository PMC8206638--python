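"""Cohort-level analysis: metric change, membership tables, outcome screen.

Runs six synthetic subjects (planted rich-club degrees 3..8, outcome
negatively coupled to the planted degree) through both timepoints and the
group statistics: per-metric paired t-tests, hub / rich-club membership
tables with exact McNemar tests, and the Spearman screen of baseline metrics
against drinking.
"""

from megnet import CohortSpec, PipelineConfig, generate_cohort, run_cohort, run_subject

spec = CohortSpec(seed=7)
subjects = generate_cohort(spec)
config = PipelineConfig(
    n_surrogate_pairs=200, n_random_networks=100, n_louvain_runs=100, master_seed=7
)

baseline = {s.subject_id: run_subject(s.baseline, config) for s in subjects}
follow_up = {s.subject_id: run_subject(s.free_access, config) for s in subjects}
outcomes = {s.subject_id: s.outcome_g_per_kg for s in subjects}

report = run_cohort(baseline, follow_up, outcomes, config)

print("metric summary (mean over subjects):")
print(report.metric_summary[["baseline_mean", "follow_up_mean"]].round(3).to_string())
print()
print("baseline-metric vs drinking screen (Spearman, exact p at n=6):")
print(report.outcome_screen[["rho", "p"]].round(3).to_string())
print()
print("rich-club membership counts (regions in >= 3 subjects at either timepoint):")
print(report.rich_club_table.to_frame().to_string())
print()
rho = report.outcome_screen.loc["rich_club_min_degree", "rho"]
print(f"The planted association shows up as a negative Spearman rho "
      f"({rho:.2f}) between baseline rich-club minimum degree and intake.")
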