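# Beis-line scenario: complete CI dominated by female mortality,
# imperfect maternal transmission, 50% initial infection.
sigma_fm: 0.98
sigma_md: 0.02
mu: 0.018
omega0: 0.5
replicates: 100
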