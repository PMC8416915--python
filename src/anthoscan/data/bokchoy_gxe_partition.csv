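source,destructive_pct,destructive_stars,hyperspectral_pct,hyperspectral_stars
genotype,77.7,*,59.2,*
environment,6.7,,11.1,
gxe,10.8,**,26.6,***
residual,4.8,***,2.9,***
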