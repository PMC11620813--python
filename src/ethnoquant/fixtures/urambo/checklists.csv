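study_label,region,other_total,present_total,common,ji_printed
Maritime,Togo,98,42,12,7.9
Osun State,Nigeria,87,42,8,5.8
Maputaland,South Africa,30,42,4,5.3
"Kamuli, Kisoro, and Nakapiripirit",Uganda,88,42,7,5.1
Kisumu,Kenya,44,42,4,4.4
Oyo State,Nigeria,26,42,3,4.2
Oran,Algeria,65,42,4,3.6
Oum Rbai,Morocco,66,42,3,2.7
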