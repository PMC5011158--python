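# SYNTHETIC RECONSTRUCTION of the 11-flavonoid external test set.
# Compound names are the printed ones; structures are the standard
# literature structures for those names (stereochemistry/protonation of
# the originals is unstated, and "silymarin" is represented by its major
# constituent silybin). One SMILES and an id per line.
O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21 naringenin
O=C1C(O)=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c21 quercetin
O=C1C(O)=C(c2ccc(O)cc2O)Oc2cc(O)cc(O)c21 morin
COc1cc(C2Oc3ccc(C4Oc5cc(O)cc(O)c5C(=O)C4O)cc3OC2CO)ccc1O silymarin
O=C(OC1Cc2c(O)cc(O)cc2OC1c1cc(O)c(O)c(O)c1)c1cc(O)c(O)c(O)c1 EGCG
O=C(OC1Cc2c(O)cc(O)cc2OC1c1ccc(O)c(O)c1)c1cc(O)c(O)c(O)c1 ECG
O=C1c2c(O)cc(O)cc2OC=C1c1ccc(OC)cc1 biochenin_A
O=C1CC(c2ccc(OC)c(O)c2)Oc2cc(OC3OC(COC4OC(C)C(O)C(O)C4O)C(O)C(O)C3O)cc(O)c21 hesperidin
O=C1C=C(c2ccc(OC)c(OC)c2)Oc2c(OC)c(OC)c(OC)c(O)c21 demethylnobiletin
O=C1C(OC)=C(c2ccc(OC)c(OC)c2)Oc2c(OC)c(OC)c(OC)c(O)c21 5HHMF
O=C1C=C(c2ccc(OC)c(OC)c2)Oc2c(OC)c(OC)c(OC)c(OC)c21 nobiletin
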