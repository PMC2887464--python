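assay,category_a,category_b,group_label
seed_set,171,507,group_a
progeny,327,25,group_a
seed_set,16,250,group_b_simplex
progeny,321,86,group_b_simplex
seed_set,309,232,group_b_triplex
progeny,208,0,group_b_triplex
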