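# Example ysrna run: mature-sperm-head default truth configuration,
# four-arm treatment panel, 100k reads.
reference:
  synthetic:
    lengths: [112, 101, 93, 83]
    stem_len: 10
    seed: 0
simulate:
  preset: sperm_head
  n_reads: 100000
  seed: 1
  treatments: [NONE, OXIDATION_BETA_ELIM, PNK, RPPH]
  p_pnk_5p_dephos: 0.8
quantify:
  min_len: 20
  max_len: 50
  adapter: null
infer:
  thresholds:
    floor: 1.0
    protected_threshold: 0.5
    gain_threshold: 2.0
    loss_threshold: 0.5
profile:
  plot: false
outdir: runs/sperm_head_demo
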