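category,species,CV
Animal bite,Periploca graeca L.,1.67
Animal bite,Tecomella undulata (Sm.) Seem.,1
Digestive,Ferula assa-foetida Boiss.,4.27
Digestive,Ziziphus sp.,0.45
Fractures,Astragalus fasciculifolius Boiss.,1.3
Fractures,Otostegia persica (Burm.) Boiss.,0.5
Grass tetany,Camellia sinensis (L.) Kuntze,0.67
Grass tetany,Ferula assa-foetida Boiss.,0.67
Grass tetany,Phoenix dactylifera L.,0.67
Increasing milk production,Amygdalus lycioides Spach,0.66
Infected wound,Capparis spinosa L.,0.6
Infected wound,Ferula assa-foetida Boiss.,0.6
Muscle and joint pain,Ferula assa-foetida Boiss.,3.22
Muscle and joint pain,A. lycioides Spach,0.44
Respiratory,Ferula assa-foetida Boiss.,1
Respiratory,Trigonella foenum-graecum L.,1
Scabies,Eruca sativa Miller,2
Udder problems,T. undulata (Sm.) Seem,1
Urinary retention,Crataegus aronia (L.) Steud.,2
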