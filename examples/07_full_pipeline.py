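"""End-to-end pipeline on a simulated study: distances, genetics, Mantel
table, RCM, DISTLM and migration, with all artifacts written to disk."""

from landgenkit import MCMCConfig, PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    output_dir="pipeline_demo",
    simulation=SimulationConfig(
        n_populations=4,
        n_individuals_per_pop=(15, 15, 15, 15),
        n_loci=10,
        n_generations=60,
        pop_sizes=50,
        rng_seed=0,
        raster_shape=(30, 30),
    ),
    subgroup="all",
    seed=7,
    n_perm_mantel=999,
    n_perm_distlm=199,
    n_perm_rcm=99,
    mcmc=MCMCConfig(n_iter=50_000, burn_in=10_000, thin=100, n_chains=2, seed=1),
)
bundle = run_pipeline(cfg)

print("stages run:", ", ".join(bundle["manifest"]["stages"]))
print("skipped:   ", ", ".join(bundle["manifest"]["skipped"]) or "none")
print("\nMantel summary (hypothesis x response):")
for row in bundle["mantel"]:
    print(
        f"  {row['hypothesis']:10s} vs {row['response']:12s} "
        f"r = {row['mantel_r']:+.3f}  p = {row['p']:.4f} ({row['tail']})"
    )
print(f"\nartifacts in {cfg.output_dir}/ (matrices, tables, manifest.json)")
# Re-running this script with the same config reproduces every file
# byte-for-byte; the manifest records inputs, seeds and skipped stages.
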