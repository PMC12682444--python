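category,species,FL
Animal bite,Tecomella undulata (Sm.) Seem.,100
Animal bite,Teucrium polium L. (C),100
Animal bite,Periploca graeca L.,83.33
Digestive,Achillea eriophora DC.,100
Digestive,Amygdalus lycioides Spach,40
Digestive,Coffea arabica L.,100
Digestive,Ephedra pachyclada Boiss.,100
Digestive,Haplophyllum laristanicum C.C.Towns.,75
Digestive,Ferula assa-foetida Boiss.,81.03
Digestive,Trigonella foenum-graecum L.,50
Digestive,Triticum aestivum L.,33.33
Digestive,Zataria multiflora Boiss.,100
Digestive,Ziziphus nummularia (Burm.f.) Wight. & Arn.,100
Digestive,Ziziphus spina-christi (L.) Desf.,100
Epistaxis,A. lycioides Spach,20
Epistaxis,E. pachyclada Boiss.,100
Epistaxis,Ferula assa-foetida Boiss.,1.72
Fever,Citrus × aurantiifolia (Christm.) Swingle,100
Fractures,Amygdalus scoparia Spach,100
Fractures,Astragalus fasciculifolius Boiss.,92.86
Fractures,Capparis spinosa L.,40
Fractures,Curcuma longa L.,100
Fractures,Ferula assa-foetida Boiss.,3.45
Fractures,Glycyrrhiza glabra L.,100
Fractures,Otostegia persica (Burm.) Boiss.,100
Fractures,Prunus amygdalus Batsch,100
Fractures,Triticum aestivum L.,66.67
Fractures,P. graeca L.,16.67
Grass tetany,Camellia sinensis (L.) Kuntze,100
Grass tetany,Ferula assa-foetida Boiss.,3.45
Grass tetany,Phoenix dactylifera L.,100
Increasing milk production,A. lycioides Spach,40
Increasing milk production,E. pachyclada Boiss.,100
Increasing milk production,Ferula assa-foetida Boiss.,1.72
Infected wound,A. fasciculifolius Boiss.,14.29
Infected wound,Calotropis procera (Aiton) W.T.Aiton,100
Infected wound,C. spinosa L.,60
Infected wound,Curcuma longa L.,100
Infected wound,Ferula assa-foetida Boiss.,5.17
Lambing,A. lycioides Spach,20
Lambing,Matricaria aurea (Loefl.) Sch.Bip.,100
Lambing,C. spinosa L.,20
Muscle and joint pain,A. lycioides Spach,80
Muscle and joint pain,Berberis sp.,100
Muscle and joint pain,E. pachyclada Boiss.,100
Muscle and joint pain,H. laristanicum C.C.Towns.,25
Muscle and joint pain,Ferula assa-foetida Boiss.,50
Muscle and joint pain,Ficus johannis Boiss.,100
Muscle and joint pain,O. persica (Burm.) Boiss.,20
Muscle and joint pain,Sesamum indicum L.,100
Muscle and joint pain,Trigonella foenum-graecum L.,50
Respiratory,Ferula assa-foetida Boiss.,3.45
Respiratory,Trigonella foenum-graecum L.,100
Scabies,Eruca sativa Miller,100
Udder problems,Matricaria aurea (Loefl.) Sch.Bip.,100
Udder problems,Ferula assa-foetida Boiss.,1.72
Udder problems,T. undulata (Sm.) Seem.,100
Urinary retention,Crataegus aronia (L.) Steud.,100
Weaning,A. fasciculifolius Boiss.,7.14
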