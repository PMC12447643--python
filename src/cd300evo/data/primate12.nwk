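((((Macaca_mulatta:0.015,Papio_anubis:0.015):0.01,Piliocolobus_tephrosceles:0.025):0.02,((Homo_sapiens:0.012,Pan_troglodytes:0.012):0.018,Hylobates_moloch:0.03):0.015):0.055,(Callithrix_jacchus:0.03,Aotus_nancymaae:0.03):0.07,((Lemur_catta:0.05,Microcebus_murinus:0.05):0.03,(Nycticebus_coucang:0.06,Otolemur_garnettii:0.06):0.02):0.06);
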