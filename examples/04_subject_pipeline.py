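"""One subject end-to-end: source series -> gated network -> metric record.

Generates a subject whose coupling graph contains a planted rich club, runs
the full single-subject pipeline (surrogate null, wPLI gating, S-threshold,
metric battery), and prints the resulting record alongside ground truth.
"""

from megnet import PipelineConfig, generate_cohort, run_subject
from megnet.synthetic import CohortSpec

spec = CohortSpec(n_subjects=3, planted_min_degrees=(4, 6, 8), seed=5)
subject = generate_cohort(spec)[1]  # planted minimum degree 6

config = PipelineConfig(
    n_surrogate_pairs=300,   # library default is 5000; smaller for a quick demo
    n_random_networks=100,
    n_louvain_runs=100,
    master_seed=42,
)
result = run_subject(subject.baseline, config)
m = result.metrics

print(f"subject {m.subject_id} ({m.timepoint}): {m.n_nodes} ROIs, "
      f"{m.n_edges} edges kept (target {result.provenance['target_edges']}, "
      f"{result.provenance['n_candidates_gated']} candidates passed the gate)")
print(f"clustering {m.clustering_coefficient:.3f}, efficiency {m.global_efficiency:.3f}, "
      f"assortativity {m.assortativity:.3f}")
print(f"modules (mean) {m.n_modules_mean:.2f}, mean connection freq "
      f"{m.mean_connection_frequency:.1f} Hz")
print(f"band counts: {m.band_counts}")
print(f"hubs: {m.hubs}")
print(f"rich club: {m.rich_club.n_nodes} nodes, min degree {m.rich_club.min_degree} "
      f"(planted {subject.planted_min_degree}), coefficient {m.rich_club.coefficient:.2f}")
print()
print("The recovered rich-club minimum degree tracks the planted club degree;")
print("spurious noise edges admitted by the density threshold can nudge it up.")
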