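# template: hanlon-bpr scoring sheet
# method: paho
# label: 12-country pilot consensus means (illustration)
rater,group,program_id,program_name,A,B,C,E,F
consensus,disease-oriented,1.1,HIV/AIDS and STIs,5,13.6,6.6,3.1,1
consensus,non-disease-oriented,4.1,"Health governance and financing; national health policies, strategies, and plans",8.3,13.4,7.1,4.1,1.1
consensus,non-disease-oriented,5.1,Alert and response capacities (for IHR),6.2,14.4,7.6,3.1,1.1
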