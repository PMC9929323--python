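# Small end-to-end demo: simulate an octamer pool, normalize with the
# self-consistent poly-G reference, fit all tetramer classes and invert the
# quench-extended dimer model.  Runs in about a minute on one CPU.
seed: 7
outdir: uvpool_demo
k_list: [4]
pool:
  depth: 200000
  bias_sigma: 1.0
doses:
  n: 10
  d_max: 250.0
stages:
  simulate: true
  via_fastq: false
fit:
  model: auto
invert:
  k: 4
  context: pool
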