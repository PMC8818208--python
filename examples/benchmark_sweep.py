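"""Run a small configuration sweep and rank the configurations.

Generates 100 synthetic admissions (25 diseases, half-noise profiles),
evaluates a representative set of similarity configurations against the
shared-primary-diagnosis labels, and prints the evaluation table.
"""

from phenosim import (
    SimilarityConfig,
    SyntheticSpec,
    correlate_metrics,
    generate_benchmark,
    results_frame,
    run_benchmark,
)

spec = SyntheticSpec(
    seed=1, n_admissions=100, n_diseases=25,
    min_admissions_per_diagnosis=2, noise_fraction=0.5,
)
graph, _, admissions, corpus = generate_benchmark(spec)

configs = [
    SimilarityConfig("jaccard"),
    SimilarityConfig("ui"),
    SimilarityConfig("gic", ic="resnik"),
    SimilarityConfig("gic", ic="seco"),
    SimilarityConfig("avg", "resnik", "resnik"),
    SimilarityConfig("bma", "resnik", "resnik"),
    SimilarityConfig("max", "rada"),
    SimilarityConfig("min", "rada"),
]
results = run_benchmark(graph, corpus, admissions, configs)

frame = results_frame(results)
cols = ["config_id", "auc", "mrr0", "mrrna", "a10", "n_matchable"]
print(frame[cols].round(3).to_string(index=False))

r, p = correlate_metrics(results, "auc", "a10")
print(f"\nPearson r between AUC and A@10 across configs: {r:.3f} (p = {p:.2g})")
print("\nAUC measures the global ranking of all shared-diagnosis pairs;")
print("MRR and A@10 reward a highly ranked first match per admission.")
print("MAX/MIN aggregation saturates on noisy profiles and stays near 0.5.")
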