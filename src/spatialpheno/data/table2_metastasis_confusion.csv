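stained_phenotype,excluded,ignored,inflamed
excluded,1,1,0
ignored,0,3,1
inflamed,0,0,6
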