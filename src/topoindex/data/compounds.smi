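# Study compounds, published-table row order: SMILES<TAB>name<TAB>group
# Kekulé drawings. Tautomeric NH placement for allopurinol/oxypurinol follows
# the 1,2-dihydro drawing selected by exhaustive enumeration against the
# published index table (see docs/methods.md); nitro groups are neutral
# pentavalent N(=O)=O. Ailanthone is a synthetic reconstruction from the
# published constitution (no structure is printed in the source table).
O=C1N=CN=C2NNC=C12	Allopurinol	hypouricemic
O=C1NC(=O)N=C2NNC=C12	Oxypurinol	hypouricemic
CC(C)COc1ccc(-c2nc(C)c(C(=O)O)s2)cc1C#N	Febuxostat	hypouricemic
CC12CCC(O)CC1=CCC1C2CCC2(C)C1CC=C2c1cccnc1	Abiraterone	anti-androgen
CC(O)(CS(=O)(=O)c1ccc(F)cc1)C(=O)Nc1ccc(C#N)c(C(F)(F)F)c1	Bicalutamide	anti-androgen
CC(C)C(=O)Nc1ccc(N(=O)=O)c(C(F)(F)F)c1	Flutamide	anti-androgen
CC1(C)NC(=O)N(c2ccc(N(=O)=O)c(C(F)(F)F)c2)C1=O	Nilutamide	anti-androgen
Cc1oncc1C(=O)Nc1ccc(C(F)(F)F)cc1	Leflunomide	anti-androgen
CC(O)=C(C#N)C(=O)Nc1ccc(C(F)(F)F)cc1	Teriflunomide	anti-androgen
C=C1C(O)C2(O)OCC34C(CC5C(C)=CC(=O)C(O)C5(C)C23)OC(=O)CC14	Ailanthone	anti-androgen
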