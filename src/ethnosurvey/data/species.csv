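species_id,accepted_name,family,synonyms,voucher
achillea-eriophora,Achillea eriophora DC.,Asteraceae,,2008
prunus-eburnea,Prunus eburnea (Spach) Aitch.,Rosaceae,Amygdalus lycioides Spach|Amygdalus lycioides,8054
amygdalus-scoparia,Amygdalus scoparia Spach,Rosaceae,Prunus scoparia (Spach) C.K. Schneid.|Prunus scoparia,14059
matricaria-aurea,Matricaria aurea (Loefl.) Sch.Bip.,Asteraceae,,15063
astragalus-fasciculifolius,Astragalus fasciculifolius Boiss.,Fabaceae,,1736
berberis-sp,Berberis sp.,Berberidaceae,,
calotropis-procera,Calotropis procera (Aiton) W.T.Aiton,Asclepiadaceae,,3324
camellia-sinensis,Camellia sinensis (L.) Kuntze,Theaceae,Camellia sinensis (L.),
capparis-spinosa,Capparis spinosa L.,Capparidaceae,,1393
citrus-aurantiifolia,Citrus × aurantiifolia (Christm.) Swingle,Rutaceae,Citrus x aurantiifolia (Christm.) Swingle,
coffea-arabica,Coffea arabica L.,Rubiaceae,,
crataegus-aronia,Crataegus aronia (L.) Steud.,Rosaceae,,14186
curcuma-longa,Curcuma longa L.,Zingiberaceae,,
ephedra-pachyclada,Ephedra pachyclada Boiss.,Ephedraceae,,5827
eruca-sativa,Eruca sativa Miller,Brassicaceae,Eruca sativa Mill.,9776
ferula-assa-foetida,Ferula assa-foetida Boiss.,Apiaceae,,16371
ficus-johannis,Ficus johannis Boiss.,Moraceae,,
glycyrrhiza-glabra,Glycyrrhiza glabra L.,Fabaceae,,15485
haplophyllum-laristanicum,Haplophyllum laristanicum C.C.Towns.,Rutaceae,,25000
otostegia-persica,Otostegia persica (Burm.) Boiss.,Lamiaceae,Otostegia persica (Burm.f.) Boiss.,14093
periploca-graeca,Periploca graeca L.,Apocynaceae,,7823
phoenix-dactylifera,Phoenix dactylifera L.,Arecaceae,,3649
prunus-amygdalus,Prunus amygdalus Batsch,Rosaceae,,
sesamum-indicum,Sesamum indicum L.,Pedaliaceae,,
tecomella-undulata,Tecomella undulata (Sm.) Seem.,Bignoniaceae,,22400
teucrium-polium,Teucrium polium L. (C),Lamiaceae,Teucrium polium L.,14428
trigonella-foenum-graecum,Trigonella foenum-graecum L.,Fabaceae,,10267
triticum-aestivum,Triticum aestivum L.,Poaceae,,
zataria-multiflora,Zataria multiflora Boiss.,Lamiaceae,,16168
ziziphus-nummularia,Ziziphus nummularia (Burm.f.) Wight. & Arn.,Rhamnaceae,,4776
ziziphus-spina-christi,Ziziphus spina-christi (L.) Desf.,Rhamnaceae,Ziziphus spina-christi (L.) Desf,3431
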