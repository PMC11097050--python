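code,description
L15,Knee symptoms or complaints
L95,Osteoporosis
L90,Osteoarthritis of the knee
N17,Vertigo or dizziness
L14,Leg or thigh symptoms or complaints
K90,Stroke or cerebrovascular accident
L73,Fracture: tibia or fibula
L03,Low back symptoms or complaints without radiation
L89,Osteoarthritis of the hip
L76,Fracture: other
R96,Asthma
L79,Sprain or strain of other joints
L74,Fracture: hand or foot bone
L16,Ankle symptoms or complaints
L97,Chronic internal knee derangement
N18,Paralysis or weakness
L84,Osteoarthritis of the spine
L77,Sprain or strain of the ankle
L75,Fracture: femur
L70,Infections musculoskeletal system
L78,Sprain or strain of the knee
P01,"Feeling anxious, nervous, tense, or inadequate"
P02,Acute stress or transient situational disturbance
P20,"Disturbances of memory, concentration, or orientation"
P74,Anxiety disorder or anxiety state
Z18,Illness problem with a child
Z19,Loss or death of a child
P06,Disturbances of sleep or insomnia
Z15,Loss or death of a partner
A80,Accident or injury NOS
P03,Feeling depressed
P99,Other mental or psychological disorder
P72,Schizophrenia
P76,Depressive disorder
P73,Affective psychosis
Z25,Problems resulting from assaults or harmful events
P04,Feeling or behaving irritable or angry
P77,Suicide attempt
P98,Other or unspecified psychoses
P70,Dementia
K86,Uncomplicated hypertension
T90,Diabetes mellitus type 2
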