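# Synthetic TTO valuation run: all 242 impaired states, 50 respondents per
# state, Gaussian disutility noise with SD 0.2, no clipping.
n_respondents: 50
noise_sd: 0.2
seed: 2012
clip: null
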