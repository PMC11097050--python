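code,description
817,HbA1c
372,fasting glucose
560,BMI
1744,systolic BP
1740,diastolic BP
542,LDL cholesterol
1401,follow dietary advice
1402,advice healthy food given
1403,advice physical activity given
K93,left foot amputation
K94,right foot amputation
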