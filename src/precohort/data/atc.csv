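code,description
A10BA02,metformin
A10BB09,gliclazide
A10BB03,tolbutamide
A10BB12,glimepiride
A10BX02,repaglinide
A10BH01,sitagliptin
A10AB05,insulin aspart
A10AE06,insulin degludec
A10AE05,insulin detemir
A10AE04,insulin glargine
A10AB01,insulin (human)
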