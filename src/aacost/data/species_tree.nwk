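((Scer:0.06,Spar:0.08):0.10,Smik:0.15,Sbay:0.20);
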