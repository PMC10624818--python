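# Full-pipeline configuration (see recovnet.pipeline.RunConfig for all keys).
# Generate matching inputs first:  recovnet synth --rows 10 --cols 10 --seed 0 --out demo
out_dir: out
seed: 0
geojson: demo/units.geojson
durations_csv: demo/durations.csv
demographics_csv: demo/demographics.csv
contiguity: queen

baseline_start: 2017-08-01
baseline_end: 2017-08-21
week_origin: 2017-08-27

baseline_runs: 1000
stage1_eta: 10
stage1_max_generations: 5000
stage2_eta: 10
stage2_max_generations: 2000
multiplier_percents: [1, 3, 5, 10]
lisa_permutations: 999
lisa_alpha: 0.05
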