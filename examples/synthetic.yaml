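# Bundled synthetic-study configuration (reduced sizes for a quick run)
seed: 11
sim:
  n_streams: 12
  n_bears:
    grizzly: {male: 20, female: 6}
    black: {male: 22, female: 5}
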