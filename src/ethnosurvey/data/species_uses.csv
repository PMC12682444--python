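species,family,use_description,local_categories,plant_part,route,literature_terms,label,provisional
Phoenix dactylifera L.,Arecaceae,Treatment of grass tetany in livestock,grass tetany,fruit,oral,poisoning treatment; endo- and ectoparasitic; eye diseases including conjunctivitis; wounds together with wheat,divergent,yes
Calotropis procera (Aiton) W.T.Aiton,Asclepiadaceae,Infected wounds that have developed worms,infected wound,resin,topical,mange; musculoskeletal disorders; dermatological disorders,corroborated,yes
Achillea eriophora DC.,Asteraceae,Diarrhea,digestive,aerial parts,oral,bloating,corroborated,yes
Matricaria aurea (Loefl.) Sch.Bip.,Asteraceae,Pain and swelling in the postpartum udder; wound healing,lambing; udder problems,aerial parts,vapor,,novel,no
Ferula assa-foetida Boiss.,Apiaceae,"Cough, parasites, muscle stiffness, discontinued milk (Shirvarak)",digestive; epistaxis; fractures; grass tetany; increasing milk production; infected wound; muscle and joint pain; respiratory; udder problems,root,oral,intestinal worm elimination; increasing milk production,corroborated,no
Periploca graeca L.,Apocynaceae,Animal bite; livestock fracture,animal bite; fractures,aerial parts,topical,,novel,no
Berberis sp.,Berberidaceae,Muscle pain,muscle and joint pain,root,oral,,novel,no
Tecomella undulata (Sm.) Seem.,Bignoniaceae,Animal bite caused by lizard,animal bite; udder problems,bark/resin,topical,,novel,no
Eruca sativa Miller,Brassicaceae,Scabies disease in camels,scabies,seed,topical,tick infestation,corroborated,yes
Capparis spinosa L.,Capparidaceae,Animal fractures,fractures,aerial parts,topical,joint pain killer (horses); respiratory problems; ulcer; dysentery; sore eyes; toothache,divergent,no
Capparis spinosa L.,Capparidaceae,Eliminating worms and external wound infections; uterine wounds,infected wound; lambing,aerial parts,topical,joint pain killer (horses); respiratory problems; ulcer; dysentery; sore eyes; toothache,divergent,no
Astragalus fasciculifolius Boiss.,Fabaceae,Fractures; weaning livestock,fractures; infected wound; weaning,bark/root/resin,topical,,novel,no
Glycyrrhiza glabra L.,Fabaceae,Fractures and bruises,fractures,root/aerial part,oral,diarrhea; relieving pain and swelling in dislocations and bruises; treating gastritis in horses; gastrointestinal diseases; otitis (horses); stomach swelling in horses; cough; bronchitis; toothache; enteritis; arthritis; endo- and ectoparasitic,corroborated,yes
Trigonella foenum-graecum L.,Fabaceae,"Severe diarrhea, cough, and muscle cramps",digestive; muscle and joint pain; respiratory,seed,oral,diarrhea; mastitis; endo- and ectoparasitic; wound; colic; paralysis; jaundice; gallbladder disorders; poisoning; increase lactation; cure prolapse of the uterus,corroborated,yes
Otostegia persica (Burm.) Boiss.,Lamiaceae,Fractures,fractures; muscle and joint pain,stem,topical,,novel,no
Teucrium polium L. (C),Lamiaceae,Animal bites (wolf),animal bite,aerial parts,topical,gastrointestinal diseases (cattle and sheep); constipation; cough; asthma; vomiting; abdominal pain; wounds,divergent,yes
Zataria multiflora Boiss.,Lamiaceae,Diarrhea,digestive,leaves,oral,,novel,no
Ficus johannis Boiss.,Moraceae,Joint pain; fracture,muscle and joint pain,fruit/leaves,oral,,novel,no
Sesamum indicum L.,Pedaliaceae,Muscle stiffness and pain,muscle and joint pain,seed,nasal,diarrhea,divergent,yes
Triticum aestivum L.,Poaceae,Diarrhea,digestive; fractures,seed,oral,mastitis; enhancement of lactation; bloating; infection; indigestion; anemia; rickets; scabies,corroborated,yes
Ziziphus nummularia (Burm.f.) Wight. & Arn.,Rhamnaceae,Poisoning,digestive,root,oral,preventing hair loss; mild skin disorders,divergent,yes
Ziziphus spina-christi (L.) Desf.,Rhamnaceae,Diarrhea and strengthening the intestinal villi,digestive,leaves,oral,preventing hair loss; mild skin disorders,divergent,yes
Crataegus aronia (L.) Steud.,Rosaceae,Urinary retention,urinary retention,fruit,oral,,novel,no
Prunus amygdalus Batsch,Rosaceae,Fractures,fractures,fruit,topical,,novel,no
Prunus eburnea (Spach) Aitch.,Rosaceae,"Joint pain, infections, intestinal worms; overall health and milk production",digestive; epistaxis; increasing milk production; lambing; muscle and joint pain,whole plant/root,oral,leishmaniasis; Oestrus ovis larvae (sheep),corroborated,yes
Prunus scoparia (Spach) C.K. Schneid.,Rosaceae,Fractures,fractures,fruit,topical,,novel,no
Coffea arabica L.,Rubiaceae,Diarrhea,digestive,seed,oral,wound; cough; sore eyes; jaundice; urinary problems; sunburn,divergent,yes
Haplophyllum laristanicum C.C.Towns.,Rutaceae,Severe diarrhea in winter; muscle cramps,digestive; muscle and joint pain,aerial parts,oral,,novel,no
Citrus × aurantiifolia (Christm.) Swingle,Rutaceae,Fever,fever,fruit,oral,,novel,no
Camellia sinensis (L.) Kuntze,Theaceae,Grass tetany in livestock,grass tetany,leaves,oral,stomach ache; endo- and ectoparasitic; flatulence; ulcer; constipation; flu; fever,divergent,yes
Curcuma longa L.,Zingiberaceae,"Fractures, infected wound",fractures; infected wound,rhizome,topical,mastitis; wound treatment; joint pain; jaundice; enteritis; swellings; caprine arthritis encephalitis palliative; proud flesh; infectious wound; pyometra,corroborated,yes
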