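center_cm1,tol_cm1,assignment,sign
734,5,tryptophan ring breathing,negative
855,5,tryptophan ring breathing,negative
1233,5,amide III beta-sheet,negative
1316,5,amide III alpha-helix,negative
1559,5,tryptophan indole ring (amide II region),negative
1008,5,phenylalanine phenyl ring,positive
1034,5,phenylalanine phenyl ring,positive
1181,5,indole ring,positive
1410,5,carboxylate ester stretch,positive
1449,5,CH deformation,positive
1603,5,phenyl ring,positive
1735,5,C=O stretch,positive
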