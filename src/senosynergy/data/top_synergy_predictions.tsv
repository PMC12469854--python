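drugA_Name	drug_B_Name	Predicted_Synergy_Score
Temsirolimus	Nitazoxanide	13.28
Temsirolimus	Fisetin	11.86
Cantharidin	Fisetin	10.35
Fisetin	Enoxacin	9.89
Cantharidin	ABT-737	9.70
Fisetin	Azithromycin	9.64
Panobinostat	Cantharidin	9.62
Temsirolimus	Rotenone	9.60
Temsirolimus	Azithromycin	9.14
Cantharidin	Enoxacin	8.32
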