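attribute,group,n,percent,mean_score,sd_score,p_value
gender,male,45,81.8,7.3,0.6,0.084
gender,female,10,18.2,6.9,0.4,
age_group,<20,3,5.5,5.9,0.8,0.001
age_group,21-40,26,47.3,6.1,0.5,
age_group,41-60,19,34.5,8.8,0.7,
age_group,>60,7,12.7,9.3,0.3,
education,illiterate,7,12.7,8.9,0.7,0.001
education,primary,44,80.0,7.7,0.4,
education,secondary,3,5.5,5.9,0.3,
education,tertiary,1,1.8,3.1,0.6,
experience_group,<5,10,18.2,3.7,0.9,0.001
experience_group,5-10,22,40.0,6.6,0.6,
experience_group,11-15,11,20.0,8.5,0.3,
experience_group,>15,12,21.8,10.6,0.8,
knowledge_source,family,37,67.3,,,
knowledge_source,herbalist,13,23.6,,,
knowledge_source,divine,5,9.1,,,
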