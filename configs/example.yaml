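# Example configuration for `obsim run --config configs/example.yaml`.
# Any omitted key falls back to the documented default.
model:
  n_mc: 100
  n_gc_init: 400
  n_add: 4
  n_shuffles: 500
protocol:
  name: perceptual_learning
  options:
    growth_days: 30
    enrichment_days: 10
    post_days: 30
seed: 0
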