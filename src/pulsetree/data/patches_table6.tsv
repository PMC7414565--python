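attachment_clade	new_tips	topology
Lemur_catta;Eulemur_fulvus	Hapalemur_griseus	(Lemur_catta,(Hapalemur_griseus,Eulemur_fulvus))
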