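cohort_id	drug	pct_responders	study_id	n_patients
ccRCC	Sorafenib	12.8	NCT00586105	39
ccRCC	Bevacizumab	26.9	NCT00719264	182
Colon	Cetuximab	8.2	NCT00083720	85
lung_AC	Sorafenib	0	NCT00064350	50
Thyroid	Imatinib	25	NCT00115739	8
Thyroid	Sorafenib	11.1	NCT00126568	18
nHLymphoma	Sunitinib	0	NCT00392496	15
sarcoma	Imatinib	33	NCT00090987	30
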