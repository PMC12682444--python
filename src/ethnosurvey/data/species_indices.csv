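species,UR,UV,FC,RFC,CI,RI,NU
Achillea eriophora DC.,1,0.005,1,0.005,0.005,0.064,1
Prunus eburnea (Spach) Aitch.,10,0.05,5,0.025,0.05,0.321,5
Amygdalus scoparia Spach,1,0.005,1,0.005,0.005,0.064,1
Matricaria aurea (Loefl.) Sch.Bip.,2,0.01,1,0.005,0.01,0.12,2
Astragalus fasciculifolius Boiss.,16,0.08,14,0.07,0.08,0.287,3
Berberis sp.,1,0.005,1,0.005,0.005,0.064,1
Calotropis procera (Aiton) W.T.Aiton,1,0.005,1,0.005,0.005,0.064,1
Camellia sinensis (L.),2,0.01,2,0.01,0.01,0.073,1
Capparis spinosa L.,6,0.03,5,0.025,0.03,0.21,3
Citrus × aurantiifolia (Christm.) Swingle,1,0.005,1,0.005,0.005,0.064,1
Coffea arabica L.,1,0.005,1,0.005,0.005,0.064,1
Crataegus aronia (L.) Steud.,2,0.01,2,0.01,0.01,0.073,1
Curcuma longa L.,4,0.02,2,0.01,0.02,0.128,2
Ephedra pachyclada Boiss.,4,0.02,1,0.005,0.02,0.231,4
Eruca sativa Miller,2,0.01,2,0.01,0.01,0.073,1
Haplophyllum laristanicum C.C.Towns.,4,0.02,4,0.02,0.02,0.146,2
Ferula assa-foetida Boiss.,88,0.44,58,0.29,0.44,1,9
Ficus johannis Boiss.,1,0.005,1,0.005,0.005,0.064,1
Glycyrrhiza glabra L.,1,0.005,1,0.005,0.005,0.064,1
Otostegia persica (Burm.) Boiss.,6,0.03,5,0.025,0.03,0.154,2
Periploca graeca L.,6,0.03,6,0.03,0.03,0.163,2
Phoenix dactylifera L.,2,0.01,2,0.01,0.01,0.073,1
Prunus amygdalus Batsch,1,0.005,1,0.005,0.005,0.064,1
Sesamum indicum L.,1,0.005,1,0.005,0.005,0.064,1
Tecomella undulata (Sm.) Seem.,6,0.03,3,0.015,0.03,0.137,2
Teucrium polium L. (C),1,0.005,1,0.005,0.005,0.064,1
Trigonella foenum-graecum L.,4,0.02,2,0.01,0.02,0.184,3
Triticum aestivum L.,3,0.015,3,0.015,0.015,0.137,2
Zataria multiflora Boiss.,3,0.015,3,0.015,0.015,0.081,1
Ziziphus nummularia (Burm.f.) Wight. & Arn.,5,0.025,5,0.025,0.025,0.099,1
Ziziphus spina-christi (L.) Desf.,5,0.025,5,0.025,0.025,0.099,1
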