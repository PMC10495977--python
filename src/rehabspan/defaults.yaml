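# Committed defaults: the single source of "default hyperparameters".
# Precedence at the CLI: this file < --config YAML < command-line flags.
train:
  learning_rate: 2.0e-5
  warmup_proportion: 0.15
  batch_size: 8
  epochs: 20
  max_seq_len: 128
  seed: 0
  optimizer: adam
  max_pairs: 50
  decay: linear
  loss:
    alpha: 1.0
    beta: 1.0
    gamma: 1.0
encoder:
  d: 32
decode:
  threshold: 0.5
  max_span_len: 30
synth:
  n_sentences: 200
  vocab_size: 80
  entity_len_range: [2, 8]
  entities_per_sentence: 2
  nesting_rate: 0.1
  low_freq_target: 0.25
  sentence_len_range: [20, 40]
  distinct_types_per_sentence: true
  hard_mode: false
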