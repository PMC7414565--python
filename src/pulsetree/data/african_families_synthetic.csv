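name,taxon_class,status,widespread,dispersal_advantaged,colonized_early,crossed_eo,arrival_period
Podocnemididae,Sauropsida,extant,unknown,yes,yes,unknown,unknown
Boidae,Sauropsida,extant,unknown,no,yes,unknown,unknown
Colubridae,Sauropsida,extant,unknown,no,yes,unknown,unknown
Gekkonidae,Sauropsida,extant,unknown,no,yes,unknown,unknown
Scincomorpha,Sauropsida,extant,unknown,no,yes,unknown,unknown
Ranoidea,Amphibia,extant,unknown,no,yes,unknown,unknown
Phaethontidae,Aves,extant,unknown,yes,yes,unknown,unknown
Lorisoidea,Mammalia,extant,unknown,no,yes,unknown,unknown
Afrosoricida,Mammalia,extant,unknown,no,yes,unknown,unknown
Myzopodidae,Mammalia,extant,unknown,yes,yes,unknown,unknown
Nycteridae,Mammalia,extant,unknown,yes,yes,unknown,unknown
extant_family_01,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_02,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_03,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_04,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_05,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_06,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_07,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_08,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_09,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_10,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_11,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_12,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_13,synthetic,extant,unknown,unknown,no,unknown,unknown
extant_family_14,synthetic,extant,unknown,unknown,no,unknown,unknown
extinct_family_01,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_02,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_03,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_04,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_05,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_06,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_07,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_08,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_09,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_10,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_11,synthetic,extinct,unknown,unknown,unknown,yes,unknown
extinct_family_12,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_13,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_14,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_15,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_16,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_17,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_18,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_19,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_20,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_21,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_22,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_23,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_24,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_25,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_26,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_27,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_28,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_29,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_30,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_31,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_32,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_33,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_34,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_35,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_36,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_37,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_38,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_39,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_40,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_41,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_42,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_43,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_44,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_45,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_46,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_47,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_48,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_49,synthetic,extinct,unknown,unknown,unknown,no,unknown
extinct_family_50,synthetic,extinct,unknown,unknown,unknown,no,unknown
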