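code,document_id,document_class
3.4,NAP-NCD-2015,national_action_plan
3.5,NAP-NCD-2015,national_action_plan
3.6,NAP-NCD-2015,national_action_plan
3.7,NAP-NCD-2015,national_action_plan
3.8,NAP-NCD-2015,national_action_plan
3.10,NAP-NCD-2015,national_action_plan
3.11,NAP-NCD-2015,national_action_plan
3.12,NAP-NCD-2015,national_action_plan
3.16,NAP-NCD-2015,national_action_plan
3.17,NAP-NCD-2015,national_action_plan
3.18,NAP-NCD-2015,national_action_plan
3.19,NAP-NCD-2015,national_action_plan
3.20,NAP-NCD-2015,national_action_plan
3.21,NAP-NCD-2015,national_action_plan
3.22,NAP-NCD-2015,national_action_plan
3.23,NAP-NCD-2015,national_action_plan
3.24,NAP-NCD-2015,national_action_plan
3.25,NAP-NCD-2015,national_action_plan
3.26,NAP-NCD-2015,national_action_plan
3.29,NAP-NCD-2015,national_action_plan
3.30,NAP-NCD-2015,national_action_plan
3.31,NAP-NCD-2015,national_action_plan
3.32,NAP-NCD-2015,national_action_plan
3.33,NAP-NCD-2015,national_action_plan
3.34,NAP-NCD-2015,national_action_plan
3.35,NAP-NCD-2015,national_action_plan
3.36,NAP-NCD-2015,national_action_plan
3.37,NAP-NCD-2015,national_action_plan
3.39,NAP-NCD-2015,national_action_plan
3.40,NAP-NCD-2015,national_action_plan
3.41,NAP-NCD-2015,national_action_plan
3.43,NAP-NCD-2015,national_action_plan
3.44,NAP-NCD-2015,national_action_plan
3.46,NAP-NCD-2015,national_action_plan
3.47,NAP-NCD-2015,national_action_plan
3.48,NAP-NCD-2015,national_action_plan
3.49,NAP-NCD-2015,national_action_plan
4.9,NAP-NCD-2015,national_action_plan
4.11,NAP-NCD-2015,national_action_plan
4.14,NAP-NCD-2015,national_action_plan
4.15,NAP-NCD-2015,national_action_plan
4.17,NAP-NCD-2015,national_action_plan
4.18,NAP-NCD-2015,national_action_plan
4.19,NAP-NCD-2015,national_action_plan
4.20,NAP-NCD-2015,national_action_plan
4.21,NAP-NCD-2015,national_action_plan
4.22,NAP-NCD-2015,national_action_plan
4.25,NAP-NCD-2015,national_action_plan
4.27,NAP-NCD-2015,national_action_plan
1.1,NATDOC-MOHME-2016,other_national_document
1.2,NATDOC-MOHME-2016,other_national_document
1.4,NATDOC-MOHME-2016,other_national_document
2.1,NATDOC-MOHME-2016,other_national_document
2.3,NATDOC-MOHME-2016,other_national_document
2.4,NATDOC-MOHME-2016,other_national_document
3.1,NATDOC-MOHME-2016,other_national_document
3.2,NATDOC-MOHME-2016,other_national_document
3.3,NATDOC-MOHME-2016,other_national_document
3.9,NATDOC-HTP-2015,other_national_document
3.13,NATDOC-MOHME-2016,other_national_document
3.14,NATDOC-MOHME-2016,other_national_document
3.15,NATDOC-MOHME-2016,other_national_document
3.27,NATDOC-MOHME-2016,other_national_document
3.28,NATDOC-MOHME-2016,other_national_document
3.42,NATDOC-MOHME-2016,other_national_document
4.1,NATDOC-MOHME-2016,other_national_document
4.3,NATDOC-MOHME-2016,other_national_document
4.4,NATDOC-MOHME-2016,other_national_document
4.5,NATDOC-MOHME-2016,other_national_document
4.6,NATDOC-MOHME-2016,other_national_document
4.8,NATDOC-MOHME-2016,other_national_document
4.23,NATDOC-MOHME-2016,other_national_document
4.24,NATDOC-MOHME-2016,other_national_document
4.28,NATDOC-MOHME-2016,other_national_document
4.29,NATDOC-MOHME-2016,other_national_document
4.30,NATDOC-MOHME-2016,other_national_document
4.32,NATDOC-MOHME-2016,other_national_document
4.33,NATDOC-MOHME-2016,other_national_document
4.34,NATDOC-MOHME-2016,other_national_document
4.35,NATDOC-MOHME-2016,other_national_document
4.36,NATDOC-MOHME-2016,other_national_document
4.37,NATDOC-MOHME-2016,other_national_document
4.38,NATDOC-MOHME-2016,other_national_document
5.1,NATDOC-MOHME-2016,other_national_document
5.2,NATDOC-MOHME-2016,other_national_document
5.3,NATDOC-MOHME-2016,other_national_document
5.4,NATDOC-MOHME-2016,other_national_document
5.5,NATDOC-MOHME-2016,other_national_document
6.1,NATDOC-MOHME-2016,other_national_document
6.2,NATDOC-MOHME-2016,other_national_document
6.3,NATDOC-MOHME-2016,other_national_document
6.4,NATDOC-MOHME-2016,other_national_document
6.5,NATDOC-MOHME-2016,other_national_document
3.4,NATDOC-TAX-2016,other_national_document
3.16,NATDOC-TAX-2016,other_national_document
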