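name,taxon_class,status,widespread,dispersal_advantaged,colonized_early,crossed_eo,arrival_period
Microhylidae_a,Amphibia,extant,unknown,unknown,unknown,unknown,pre_eo
Microhylidae_b,Amphibia,extant,unknown,unknown,unknown,unknown,pre_eo
Mantellidae,Amphibia,extant,unknown,unknown,unknown,unknown,pre_eo
Ranoidea,Amphibia,extant,unknown,unknown,unknown,unknown,pre_eo
Podocnemidae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Chamaeleonidae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Gerrhosauridae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Opluridae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Gekkonidae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Scincidae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Boidae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Lamprophiidae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Typhlopidae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Xenotyphlopidae,Sauropsida,extant,unknown,unknown,unknown,unknown,pre_eo
Aepyornithidae,Aves,extant,unknown,unknown,unknown,unknown,pre_eo
Mesitornithidae,Aves,extant,unknown,unknown,unknown,unknown,pre_eo
Phaethonidae,Aves,extant,unknown,unknown,unknown,unknown,pre_eo
Psittacidae_a,Aves,extant,unknown,unknown,unknown,unknown,pre_eo
Psittacidae_b,Aves,extant,unknown,unknown,unknown,unknown,pre_eo
Lemuroidea,Mammalia,extant,unknown,unknown,unknown,unknown,pre_eo
Myzopodidae,Mammalia,extant,unknown,unknown,unknown,unknown,pre_eo
Nycteridae,Mammalia,extant,unknown,unknown,unknown,unknown,pre_eo
Plesiorycteropodidae,Mammalia,extant,unknown,unknown,unknown,unknown,pre_eo
Hyperoliidae,Amphibia,extant,unknown,unknown,unknown,unknown,post_eo
Ptychadenidae,Amphibia,extant,unknown,unknown,unknown,unknown,post_eo
Testudinae,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Crocodylidae_a,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Crocodylidae_b,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Gekkonidae_a,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Gekkonidae_b,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Scincidae_a,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Scincidae_b,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Lamprophiidae_a,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Lamprophiidae_b,Sauropsida,extant,unknown,unknown,unknown,unknown,post_eo
Acrocephalidae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Apodidae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Bernieridae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Campephagidae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Dicruridae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Motacillidae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Nectarinidae_a,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Nectarinidae_b,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Pycnonotidae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Strigidae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Sturnidae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Vangidae,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Zosteropidae_a,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Zosteropidae_b,Aves,extant,unknown,unknown,unknown,unknown,post_eo
Emballonuridae_a,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Emballonuridae_b,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Emballonuridae_c,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Eupleridae,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Hippopotamidae_a,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Hippopotamidae_b,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Hipposideridae_a,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Hipposideridae_b,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Hipposideridae_c,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Molossidae_a,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Molossidae_b,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Molossidae_c,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Molossidae_d,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Molossidae_e,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Molossidae_f,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Nesomyinae,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Pteropodidae_a,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Pteropodidae_b,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Vespertilionidae_a,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Vespertilionidae_b,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Vespertilionidae_c,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Vespertilionidae_d,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Tenrecidae,Mammalia,extant,unknown,unknown,unknown,unknown,post_eo
Ceratophryinae,Amphibia,extant,unknown,unknown,unknown,unknown,cretaceous
Bothremydidae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Podocnemidae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Mahajangasuchidae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Notosuchia_a,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Notosuchia_b,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Trematochampsidae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Cordylidae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Dromaeosauridae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Madtsoiidae_a,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Madtsoiidae_b,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Nigerophiidae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Abelisauridae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Noasauridae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Nemegtosauridae,Sauropsida,extant,unknown,unknown,unknown,unknown,cretaceous
Ornithurae,Aves,extant,unknown,unknown,unknown,unknown,cretaceous
Marsupialia,Mammalia,extant,unknown,unknown,unknown,unknown,cretaceous
Multituberculata,Mammalia,extant,unknown,unknown,unknown,unknown,cretaceous
Sudamericidae,Mammalia,extant,unknown,unknown,unknown,unknown,cretaceous
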