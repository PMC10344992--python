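term,coefficient
anchor,1.0
constant,0.071
mo2,0.036
mo3,0.161
sc2,0.082
sc3,0.152
ua2,0.032
ua3,0.057
pd2,0.086
pd3,0.329
ad2,0.124
ad3,0.325
n3,0.234
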