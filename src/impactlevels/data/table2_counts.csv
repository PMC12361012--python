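,no impact,mild impact,bothersome,high impact
no impact,6,5,0,0
mild impact,37,53,58,113
moderate impact,3,0,4,65
high impact,0,1,4,60
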