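# Maritime-monsoon scenario: 144 sites on a 100x100 grid of 2-km cells.
# Keys are keyword overrides applied to the library's scenario builder.
scenario: jiaodong
n_sites: 144
seed: 1
nx: 100
ny: 100
cell_km: 2.0
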