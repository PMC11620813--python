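category,Nur,Nt,icf_printed
cough,361,29,0.922
flu,87,8,0.919
asthma,101,10,0.910
pneumonia,28,4,0.889
colds,71,9,0.886
sore throat,18,3,0.882
tonsillitis,9,2,0.875
COVID-19,17,3,0.875
bronchitis,33,5,0.875
tuberculosis,8,3,0.714
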