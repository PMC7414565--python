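clade_tips	age_ma	source
Daubentonia_madagascariensis;Megaladapis_edwardsi;Lemur_catta;Eulemur_fulvus;Pachylemur_insignis;Varecia_variegata;Phaner_furcifer;Lepilemur_mustelinus;Lepilemur_ruficaudatus;Microcebus_murinus;Cheirogaleus_major;Archaeolemur_majori;Indri_indri;Propithecus_diadema;Palaeopropithecus_ingens;Palaeopropithecus_maximus	50	kistler
Megaladapis_edwardsi;Lemur_catta;Eulemur_fulvus;Pachylemur_insignis;Varecia_variegata;Phaner_furcifer;Lepilemur_mustelinus;Lepilemur_ruficaudatus;Microcebus_murinus;Cheirogaleus_major;Archaeolemur_majori;Indri_indri;Propithecus_diadema;Palaeopropithecus_ingens;Palaeopropithecus_maximus	31	kistler
Phaner_furcifer;Lepilemur_mustelinus;Lepilemur_ruficaudatus;Microcebus_murinus;Cheirogaleus_major;Archaeolemur_majori;Indri_indri;Propithecus_diadema;Palaeopropithecus_ingens;Palaeopropithecus_maximus	29	kistler
Phaner_furcifer;Lepilemur_mustelinus;Lepilemur_ruficaudatus;Microcebus_murinus;Cheirogaleus_major	28.5	10ktrees
Megaladapis_edwardsi;Lemur_catta;Eulemur_fulvus;Pachylemur_insignis;Varecia_variegata	27	kistler
Phaner_furcifer;Lepilemur_mustelinus;Lepilemur_ruficaudatus	25.7	10ktrees
Archaeolemur_majori;Indri_indri;Propithecus_diadema;Palaeopropithecus_ingens;Palaeopropithecus_maximus	24	kistler
Microcebus_murinus;Cheirogaleus_major	22.6	10ktrees
Indri_indri;Propithecus_diadema;Palaeopropithecus_ingens;Palaeopropithecus_maximus	21	kistler
Lemur_catta;Eulemur_fulvus;Pachylemur_insignis;Varecia_variegata	19	kistler
Indri_indri;Propithecus_diadema	17	kistler
Lemur_catta;Eulemur_fulvus	15.0	10ktrees
Lepilemur_mustelinus;Lepilemur_ruficaudatus	13.3	10ktrees
Pachylemur_insignis;Varecia_variegata	11	kistler
Palaeopropithecus_ingens;Palaeopropithecus_maximus	0.6	kistler
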