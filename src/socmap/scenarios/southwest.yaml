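# Continental scenario: 123 sites on a 100x100 grid of 2-km cells.
scenario: southwest
n_sites: 123
seed: 1
nx: 100
ny: 100
cell_km: 2.0
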