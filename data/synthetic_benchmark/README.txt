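Synthetic benchmark dataset (generated by bacrate.simulate.reference_dataset,
seed 0).  Entirely simulated — no real measurements.  It mirrors the column
structure of a literature-curated accumulation-rate compilation (per-estimate
rate table, per-species trait table, per-generation mutation-rate table,
species tree) and its post-curation sample statistics are imposed exactly so
the analysis pipeline can be checked against known values.  Regenerate with:

    bacrate simulate --seed 0 --outdir data/synthetic_benchmark
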