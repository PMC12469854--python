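drug_name	proposed_targets
Azacyclonol	Histamine
Cyclosporin A	Calcineurin, NFAT
Digoxin	Na+/K+-ATPase
Nitrofural	ROS generation
Roxithromycin	Protein homeostasis
Luteolin	PI3K/Akt, Nrf2, NF-κB
Enoxacin	TRBP
Atorvastatin	HMG-CoA, Rho/ROCK
Azithromycin	Mitochondrial translation
Nitazoxanide	phosphorylation
Adapalene	RAR/RXR nuclear receptors
Amiloride hydrochloride	NHE1, ENaC
Cantharidin	PP2A
Calmidazolium chloride	Calmodulin
Dequalinium chloride hydrate	Mitochondria membrane potential
Diphenyleneiodonium chloride	NADPH oxidase, flavoproteins
2,3-Dimethoxy-1,4-naphthoquinone	Redox cycling
Idarubicin	Topoisomerase II
JFD00244	SIRT6
Mibefradil dihydrochloride	T-type calcium channels
Piperlongumine	TrxR/GPx
Ouabain	Na+/K+-ATPase
Quercetin dihydrate	PI3K, HSP90, AMPK, Nrf2
Rottlerin	PKCδ
Rotenone	Complex I (ETC)
BIX 01294 trihydrochloride hydrate	G9a/GLP (EHMT2/1)
Tyrphostin AG 879	ErbB2, TrkA
Vincristine sulfate	Tubulin
Tanespimycin	HSP90
Geldanamycin	HSP90
Alvespimycin	HSP90
ProDrug A	unknown
JHB76B	KRAS/ERK pathway
CGP-74514A	CDK1/2
Ouabagenin	Na+/K+-ATPase
K-Strophanthin	Na+/K+-ATPase
Strophanthidin	Na+/K+-ATPase
PF-573228	FAK
LY-367265	5-HT1B/1D
Temsirolimus	mTORC1
Eltrombopag	MPL (TPO -R)
Raltegravir	HIV integrase
Venetoclax	BCL-2
EF24	NF-κB/IκB-α
Panobinostat	HDAC
Bufalin	Na+/K+-ATPase
Proscillaridin A	Na+/K+-ATPase
Cinobufagin	Na+/K+-ATPase
Peruvoside	Na+/K+-ATPase
Digitoxin	Na+/K+-ATPase
Convallotoxin	Na+/K+-ATPase
ABT-737	BCL-2, BCL-xL, BCL-w
Fisetin	PI3K, NF-κB, HIF-1α, Nrf2
Curcumin	NF-κB, Nrf2, HAT/HDAC
Dasatinib	SRC/ABL kinases
Navitoclax	BCL-2, BCL-xL
A1331852	BCL-xL
A1155463	BCL-xL
ginkgetin	JAK/STAT, NF-κB
oleandrin	Na+/K+-ATPase
periplocin	Na+/K+-ATPase
BRD-K56819078	HSP90
XL888	HSP90
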