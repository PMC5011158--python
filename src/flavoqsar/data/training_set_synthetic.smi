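# SYNTHETIC RECONSTRUCTION of the 23-flavonoid training set.
# The original training-set structure drawings are not machine-readable, so
# these are 23 well-known flavonoids with standard literature structures,
# paired in an arbitrary but fixed order with the printed observed pFAR
# values via compound number (see training_activities_synthetic.csv).
# Stereochemistry/protonation of the originals is unknown. Edit freely:
# one SMILES and an id per line; lines starting with '#' are comments.
O=C1C=C(c2ccccc2)Oc2ccccc21 flavone
O=C1CC(c2ccccc2)Oc2ccccc21 flavanone
O=C1C=C(c2ccccc2)Oc2cc(O)cc(O)c21 chrysin
O=C1C=C(c2ccc(O)cc2)Oc2cc(O)cc(O)c21 apigenin
O=C1C=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c21 luteolin
O=C1C(O)=C(c2ccccc2)Oc2cc(O)cc(O)c21 galangin
O=C1C(O)=C(c2ccc(O)cc2)Oc2cc(O)cc(O)c21 kaempferol
O=C1C(O)=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c21 quercetin
O=C1C(O)=C(c2cc(O)c(O)c(O)c2)Oc2cc(O)cc(O)c21 myricetin
O=C1C(O)=C(c2ccc(O)c(O)c2)Oc2cc(O)ccc21 fisetin
O=C1C(O)=C(c2ccc(O)cc2O)Oc2cc(O)cc(O)c21 morin
O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21 naringenin
O=C1CC(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c21 eriodictyol
O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)C1O taxifolin
O[C@H]1Cc2c(O)cc(O)cc2O[C@@H]1c1ccc(O)c(O)c1 catechin
O[C@H]1Cc2c(O)cc(O)cc2O[C@H]1c1ccc(O)c(O)c1 epicatechin
O=C1c2c(O)cc(O)cc2OC=C1c1ccc(O)cc1 genistein
O=C1c2ccc(O)cc2OC=C1c1ccc(O)cc1 daidzein
O=C1c2c(O)cc(O)cc2OC=C1c1ccc(OC)cc1 biochanin_A
O=C1CC(c2ccc(O)cc2)Oc2cc(OC3OC(CO)C(O)C(O)C3OC3OC(C)C(O)C(O)C3O)cc(O)c21 naringin
O=C1CC(c2ccc(OC)c(O)c2)Oc2cc(O)cc(O)c21 hesperetin
O=C1C=C(c2ccccc2)Oc2cc(O)c(O)c(O)c21 baicalein
O=C1C=C(c2ccc(OC)cc2)Oc2c(OC)c(OC)c(OC)c(OC)c21 tangeretin
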