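# Default lipid disease / identifier lexicon: 4 diseases + 7 identifiers.
name	kind	synonyms
Dyslipidemia	disease	dyslipidemia|dyslipidaemia
Hyperlipidemia	disease	hyperlipidemia|hyperlipidaemia
Hypercholesterolemia	disease	hypercholesterolemia|hypercholesterolaemia
Hypertriglyceridemia	disease	hypertriglyceridemia|hypertriglyceridaemia
HDL-Cholesterol	identifier	HDL-Cholesterol|HDL cholesterol|HDL-C|high-density lipoprotein cholesterol
HDL	identifier	HDL|high-density lipoprotein
LDL-Cholesterol	identifier	LDL-Cholesterol|LDL cholesterol|LDL-C|low-density lipoprotein cholesterol
LDL	identifier	LDL|low-density lipoprotein
Triglyceride	identifier	triglyceride|triglycerides
Low HDL-C	identifier	low HDL-C|low HDL cholesterol
High LDL-C	identifier	high LDL-C|high LDL cholesterol
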