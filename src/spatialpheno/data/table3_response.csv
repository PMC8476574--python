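response,excluded_ignored,inflamed
nonresponder,35,4
responder,4,6
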