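id	name	delta_mass	sites
oxidation	Oxidation	15.994915	M,W
carbamidomethyl	Carbamidomethyl	57.021464	C
phospho	Phospho	79.966331	S,T,Y
acetyl	Acetyl	42.010565	K,protein-N
methyl	Methyl	14.015650	K,R
dimethyl	Dimethyl	28.031300	K,R
trimethyl	Trimethyl	42.046950	K
deamidated	Deamidated	0.984016	N,Q
amidated	Amidated	-0.984016	peptide-C
gln_pyro_glu	Gln->pyro-Glu	-17.026549	Q
glu_pyro_glu	Glu->pyro-Glu	-18.010565	E
formyl	Formyl	27.994915	K,S,T
gg	GG (ubiquitinylation remnant)	114.042927	K
succinyl	Succinyl	100.016044	K
malonyl	Malonyl	86.000394	K
crotonyl	Crotonyl	68.026215	K
propionyl	Propionyl	56.026215	K
butyryl	Butyryl	70.041865	K
nitro	Nitro	44.985078	Y,W
sulfo	Sulfo	79.956815	S,T,Y
carbamyl	Carbamyl	43.005814	K,peptide-N
myristoyl	Myristoyl	210.198366	K
palmitoyl	Palmitoyl	238.229666	C,K
biotin	Biotin	226.077598	K
methylthio	Methylthio	45.987721	C
dehydrated	Dehydrated	-18.010565	S,T,D
silac_k8	Label:13C(6)15N(2)	8.014199	K
silac_r10	Label:13C(6)15N(4)	10.008269	R
sodium_adduct	Cation:Na	21.981943	D,E,peptide-C
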