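category,Nur,Ntaxa,ICF
Animal bite,9,5,0.5
Digestive,70,11,0.86
Epistaxis,3,3,0
Fever,1,1,0
Fractures,30,10,0.69
Grass tetany,6,3,0.6
Increasing milk production,4,3,0.33
Infected wound,11,5,0.6
Lambing,3,3,0
Muscle and joint pain,40,9,0.79
Respiratory,4,2,0.67
Scabies,2,1,1
Udder problems,5,3,0.5
Urinary retention,1,1,0
Weaning,1,1,0
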