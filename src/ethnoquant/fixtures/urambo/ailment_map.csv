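raw_label,category
influenza,flu
flu,flu
colds,colds
cold,colds
coughs,cough
cough,cough
chronic coughs,cough
whooping coughs,cough
asthma,asthma
pneumonia,pneumonia
sore throat,sore throat
throat infection,sore throat
tonsillitis,tonsillitis
covid-19,COVID-19
bronchitis,bronchitis
bronchial complaints,bronchitis
tuberculosis,tuberculosis
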