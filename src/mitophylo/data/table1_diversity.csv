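suborder,family,genera_sampled,genera_total,species_sampled,species_total
Lophioidei,Lophiidae,4,4,4,25
Antennarioidei,Antennariidae,2,12,3,45
Antennarioidei,Tetrabrachiidae,1,2,1,2
Antennarioidei,Brachionichthyidae,1,2,1,5
Antennarioidei,Lophichthyidae,0,1,0,1
Chaunacoidei,Chaunacidae,1,2,3,14
Ogcocephaloidei,Ogcocephalidae,4,10,4,68
Ceratioidei,Caulophrynidae,1,2,2,5
Ceratioidei,Neoceratiidae,1,1,1,1
Ceratioidei,Melanocetidae,1,1,2,6
Ceratioidei,Himantolophidae,1,1,2,18
Ceratioidei,Diceratiidae,2,2,2,6
Ceratioidei,Oneirodidae,4,16,4,63
Ceratioidei,Thaumatichthyidae,2,2,2,8
Ceratioidei,Centrophrynidae,1,1,1,1
Ceratioidei,Ceratiidae,2,2,2,4
Ceratioidei,Gigantactinidae,2,2,2,21
Ceratioidei,Linophrynidae,3,5,3,27
Total,(all),33,68,39,321
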