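# Curated compound structures for the case-study reactions (steroid
# 11beta-hydroxylation, tocopherol ring methylation, homogentisate ring
# cleavage). Hand-transcribed constitutional SMILES; stereo-descriptors are
# deliberately omitted because the scoring pipeline's Morgan fingerprints
# are computed achiral, so they cannot affect any score. Verify against a
# structure database (e.g. PubChem) before reusing outside this package.
name	SMILES	source
11-deoxycortisol	CC12CCC(=O)C=C1CCC1C2CCC2(C)C1CCC2(O)C(=O)CO	curated
cortisol	CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2(O)C(=O)CO	curated
cortisone	CC12CCC(=O)C=C1CCC1C2C(=O)CC2(C)C1CCC2(O)C(=O)CO	curated
17alpha-hydroxyprogesterone	CC12CCC(=O)C=C1CCC1C2CCC2(C)C1CCC2(O)C(=O)C	curated
21-deoxycortisol	CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2(O)C(=O)C	curated
alpha-tocopherol	CC(C)CCCC(C)CCCC(C)CCCC1(C)CCc2c(C)c(O)c(C)c(C)c2O1	curated
gamma-tocopherol	CC(C)CCCC(C)CCCC(C)CCCC1(C)CCc2cc(O)c(C)c(C)c2O1	curated
13-hydroxy-alpha-tocopherol	OCC(C)CCCC(C)CCCC(C)CCCC1(C)CCc2c(C)c(O)c(C)c(C)c2O1	curated
alpha-tocotrienol	CC(C)=CCCC(C)=CCCC(C)=CCCC1(C)CCc2c(C)c(O)c(C)c(C)c2O1	curated
gamma-tocotrienol	CC(C)=CCCC(C)=CCCC(C)=CCCC1(C)CCc2cc(O)c(C)c(C)c2O1	curated
homogentisate	OC(=O)Cc1cc(O)ccc1O	curated
4-maleylacetoacetate	OC(=O)/C=C\C(=O)CC(=O)CC(=O)O	curated
4-fumarylacetoacetate	OC(=O)/C=C/C(=O)CC(=O)CC(=O)O	curated
fumarate	OC(=O)/C=C/C(=O)O	curated
hydroxyquinol	Oc1ccc(O)c(O)c1	curated
maleylacetate	OC(=O)/C=C\C(=O)CC(=O)O	curated
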