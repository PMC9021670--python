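icd3,consented,consented_avoidability
L02,true,100
H25,true,95
F07,true,90
G40,true,90
K08,true,85
N18,true,85
A04,true,80
F10,true,80
R13,true,80
C44,true,75
E86,true,75
F05,true,75
F06,true,75
F20,true,75
I50,true,75
I80,true,75
J10,true,75
K25,true,75
K26,true,75
K62,true,75
S01,true,75
E87,true,70
R07,true,70
F25,false,
L03,false,
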