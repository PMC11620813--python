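informant_id,gender,age_group,education,experience_group,knowledge_source
THP01,male,21-40,secondary,11-15,family
THP02,female,21-40,primary,5-10,family
THP03,male,41-60,primary,>15,herbalist
THP04,male,>60,primary,>15,family
THP05,male,21-40,secondary,11-15,herbalist
THP06,male,21-40,primary,5-10,family
THP07,male,>60,primary,5-10,herbalist
THP08,male,>60,primary,5-10,family
THP09,male,41-60,primary,<5,herbalist
THP10,male,21-40,primary,5-10,herbalist
THP11,male,41-60,primary,>15,family
THP12,male,21-40,primary,<5,family
THP13,male,41-60,illiterate,11-15,family
THP14,male,21-40,primary,>15,divine
THP15,female,21-40,illiterate,<5,family
THP16,male,41-60,primary,11-15,family
THP17,male,>60,primary,<5,family
THP18,male,>60,primary,>15,herbalist
THP19,male,21-40,illiterate,<5,herbalist
THP20,male,41-60,primary,>15,family
THP21,female,21-40,primary,5-10,divine
THP22,male,41-60,illiterate,11-15,family
THP23,male,21-40,primary,>15,family
THP24,male,41-60,primary,>15,family
THP25,male,41-60,primary,5-10,family
THP26,female,<20,illiterate,11-15,herbalist
THP27,female,>60,primary,>15,family
THP28,male,<20,primary,5-10,divine
THP29,female,41-60,primary,5-10,family
THP30,male,21-40,primary,11-15,family
THP31,male,21-40,primary,<5,family
THP32,male,41-60,tertiary,>15,family
THP33,male,41-60,secondary,5-10,family
THP34,male,21-40,primary,5-10,family
THP35,male,>60,illiterate,5-10,family
THP36,male,21-40,primary,<5,herbalist
THP37,male,41-60,primary,5-10,family
THP38,male,<20,primary,5-10,family
THP39,male,21-40,illiterate,5-10,family
THP40,male,21-40,primary,5-10,family
THP41,female,21-40,primary,5-10,herbalist
THP42,male,21-40,primary,5-10,divine
THP43,male,41-60,primary,11-15,herbalist
THP44,male,21-40,primary,5-10,herbalist
THP45,female,21-40,primary,<5,family
THP46,male,41-60,primary,11-15,family
THP47,male,21-40,primary,<5,family
THP48,male,21-40,primary,>15,herbalist
THP49,male,21-40,primary,5-10,family
THP50,male,21-40,primary,<5,family
THP51,female,41-60,primary,11-15,family
THP52,male,41-60,primary,5-10,family
THP53,male,41-60,primary,>15,family
THP54,male,21-40,primary,11-15,family
THP55,female,41-60,primary,5-10,divine
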