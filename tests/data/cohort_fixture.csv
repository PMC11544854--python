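wound_id,patient_id,skin_type,surf1,epi1,dermal1,vasc1,surf2,epi2,dermal2,vasc2,clinical_judgment,outcome,days_to_graft
w01,p01,glabrous,0,0,0,0,0,0,0,0,superficial,healed_spontaneously,
w02,p02,glabrous,1,0,1,0,1,0,1,0,superficial,healed_spontaneously,
w03,p03,hair_bearing,1,1,1,0,1,1,1,0,superficial,healed_spontaneously,
w04,p04,hair_bearing,1,1,1,1,1,1,2,1,deep,healed_spontaneously,
w05,p05,glabrous,1,1,2,0,1,1,2,0,superficial,healed_spontaneously,
w06,p06,hair_bearing,1,1,2,1,1,1,2,2,deep,grafted,9
w07,p07,glabrous,1,1,2,2,1,1,2,2,deep,grafted,11
w08,p08,hair_bearing,1,1,2,2,1,1,2,2,deep,deep_refused_graft,
w09,p09,glabrous,1,0,2,1,,,,,superficial,healed_spontaneously,
w10,p10,hair_bearing,0,1,1,1,0,1,1,1,,healed_spontaneously,
w11,p11,glabrous,1,1,1,1,1,1,1,1,superficial,healed_spontaneously,
w12,p06,hair_bearing,1,1,2,2,1,1,2,2,deep,grafted,7
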