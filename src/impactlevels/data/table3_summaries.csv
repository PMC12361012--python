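label,n,mean,sd
No impact,46,55.8,7.1
Mild impact,59,54.8,5.7
Bothersome,66,60.7,4.6
High impact,238,66.2,5.5
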