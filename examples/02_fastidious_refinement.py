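"""Show how fastidious refinement merges satellite OTUs into abundant ones.

Runs the same community with and without the fastidious step (t_f = 2*t,
boundary b = 3) and compares OTU counts and quality: light OTUs — often
rare error variants stranded beyond t — are grafted onto heavy OTUs
through virtual linking amplicons, raising recall without hurting
precision.
"""

from ampliswarm import (
    ClusteringConfig,
    adjusted_rand,
    generate_community,
    pair_counting_metrics,
    run_clustering,
)

community = generate_community(
    n_species=12, mean_log_reads=3.5, sigma_log_reads=1.0,
    mutation_rate=0.004, length=250, rng_seed=11,
)

for label, cfg in [
    ("plain      ", ClusteringConfig(t=1)),
    ("fastidious ", ClusteringConfig(t=1, fastidious=True, boundary=3)),
]:
    result = run_clustering(community.amplicons, cfg)
    precision, recall = pair_counting_metrics(result.partition, community.labels)
    ari = adjusted_rand(result.partition, community.labels)
    print(f"{label} otus={len(result.otus):4d} grafted={len(result.grafts):4d} "
          f"precision={precision:.3f} recall={recall:.3f} ari={ari:.3f}")
print("Each grafted OTU was a light cluster (weight < 3) whose member lay "
      "within t_f=2 of a heavy-cluster amplicon — one virtual intermediate "
      "away at t=1.")
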