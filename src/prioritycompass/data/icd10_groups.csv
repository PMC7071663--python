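icd10_code,group
I20.0,cardiovascular
I25.1,cardiovascular
I10,cardiovascular
R07.4,cardiovascular
I64,cardiovascular
I50.0,cardiovascular
I25.9,cardiovascular
I21.9,cardiovascular
I48,cardiovascular
I50.9,cardiovascular
I80.2,cardiovascular
I51.6,cardiovascular
G45.9,cardiovascular
Z03.5,cardiovascular
I24.9,cardiovascular
Z51.1,cancer
N83.2,cancer
N63,cancer
D48.7,cancer
J35.3,diabetes
O24.4,diabetes
E11.5,diabetes
E14.5,diabetes
E10.9,diabetes
E11.9,diabetes
J18.9,chronic_respiratory
J44.9,chronic_respiratory
R06.0,chronic_respiratory
J45.9,chronic_respiratory
J44.1,chronic_respiratory
J21.9,chronic_respiratory
J40,chronic_respiratory
J46,chronic_respiratory
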