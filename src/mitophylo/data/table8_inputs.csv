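clade,n_species,stem_age_myr
Lophioidei,25,134.7
Ogcocephaloidei,54,129.2
Antennarioidei,66,125.6
Chaunacoidei,15,117.2
Ceratioidei,161,117.2
Lophiiformes,321,157
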