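# Demo study: four screenings of one film, audiences 87/96/104/186 in a
# 230-seat room flushed 6x/hour; ten noisy annotators, four label tracks.
# Run with:  python -c "from cinevoc.pipeline import run_pipeline;
#                       run_pipeline('configs/demo.yaml')"
outdir: results/pipeline_demo
seed: 1
film_name: Demo Feature
audiences: [87, 96, 104, 186]
film_duration_s: 7200.0
analysis_labels: [suspense, comedy]
forward_masses: [co2, m69.070]
n_annotators: 10
n_repeats: 15
n_trees: 100
window_s: 300.0
auc_min: 0.5
p_max: 0.05
make_figures: true
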