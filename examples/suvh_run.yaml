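seed: 1
outdir: demo_out
simulate:
  preset: suvh
params:
  bootstrap: 200
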