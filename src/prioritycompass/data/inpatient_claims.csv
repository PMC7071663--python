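icd10_code,admissions
I20.0,56238
I25.1,29660
I10,26819
R07.4,16363
I64,12663
I50.0,11763
I25.9,11437
I21.9,10174
I48,7187
I50.9,6906
I80.2,4048
I51.6,3794
G45.9,3412
Z03.5,3012
I24.9,2347
Z51.1,21301
N83.2,5645
N63,2242
D48.7,710
J35.3,8531
O24.4,5139
E11.5,4013
E14.5,1994
E10.9,1933
E11.9,1190
J18.9,44902
J44.9,16173
R06.0,12856
J45.9,12367
J44.1,3281
J21.9,2486
J40,2021
J46,966
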