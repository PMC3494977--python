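((Potorous_tridactylus,(Lagorchestes_conspicillatus,Wallabia_bicolor)),(Choloepus_hoffmanni,(((((Aotus_azarae,Aotus_boliviensis,Aotus_inflatus,Aotus_sp),Callimico_goeldii),((Alouatta_belzebul,Alouatta_fusca,Alouatta_palliata),Cacajao_calvus)),(Deltamys_kempi,((Taterillus_arenarius,Taterillus_petteri,Taterillus_pygargus,Taterillus_sp_1,Taterillus_sp_2,Taterillus_tranieri),(Vandeleuria_oleracea,(Mus_minutoides,Mus_musculoides))))),((Sorex_araneus_Race_A,Sorex_gemelleus),(((Choeroniscus_godmani,(Carollia_subrufa,Carolia_perspicillata)),(Mesophylla_macconnelli,(Artibeus_jamaicensis,Artibeus_lituratus,Artibeus_toltecus))),(Herpestes_auropunctatus,(Muntiacus_muntjak,(Tragelaphus_strepsiceros,(Gazella_granti,Gazella_gazella,Gazella_dorcas,Gazella_spekei,Gazella_leptoceros,Gazella_subgutturosa)))))))));
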