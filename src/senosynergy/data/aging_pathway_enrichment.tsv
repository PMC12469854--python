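term_id	description	gene_ids	count
hsa04020	Calcium signaling pathway	PLN/CASQ2/CACNA1H/MET	4
hsa04360	Axon guidance	L1CAM/MET/SLIT3	3
hsa04510	Focal adhesion	LAMA3/FLNC/MET	3
hsa05415	Diabetic cardiomyopathy	CMA1/PLN/COX4I2	3
hsa04024	cAMP signaling pathway	ADCYAP1R1/PLN/SSTR1	3
hsa04010	MAPK signaling pathway	FLNC/CACNA1H/MET	3
hsa00830	Retinol metabolism	CYP26B1/ALDH1A2	2
hsa04260	Cardiac muscle contraction	CASQ2/COX4I2	2
hsa04713	Circadian entrainment	ADCYAP1R1/CACNA1H	2
hsa04061	Viral protein interaction with cytokine and cytokine receptor	CCL21/CCL19	2
hsa04064	NF-kappa B signaling pathway	CCL21/CCL19	2
hsa04062	Chemokine signaling pathway	CCL21/CCL19	2
hsa05205	Proteoglycans in cancer	FLNC/MET	2
hsa05208	Chemical carcinogenesis—reactive oxygen species	COX4I2/MET	2
hsa04060	Cytokine-cytokine receptor interaction	CCL21/CCL19	2
hsa04151	PI3K-Akt signaling pathway	LAMA3/MET	2
hsa04080	Neuroactive ligand–receptor interaction	ADCYAP1R1/SSTR1	2
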