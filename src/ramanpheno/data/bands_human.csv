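center_cm1,tol_cm1,assignment,sign
1286,5,amide III alpha-helix,negative
1340,5,amide III alpha-helix,negative
1619,5,amide I,negative
1669,5,amide I,negative
785,5,cytosine/uracil ring breathing,positive
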