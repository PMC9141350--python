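# Example pipeline configuration for `cardiophase features --config`.
# Values shown are the defaults.
smoothing:
  ri: 3      # internal smoothing radius / lag bound, beats
  re: 4      # external smoothing radius, beats
  beta: 1    # perfect-matrix arrangement (only 1 implemented)
normalize: true  # min-max rescale RR/JT to [0, 1] before matrix construction
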