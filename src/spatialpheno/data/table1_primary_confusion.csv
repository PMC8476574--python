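stained_phenotype,excluded,ignored,inflamed
excluded,18,0,0
ignored,4,5,0
inflamed,3,0,12
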