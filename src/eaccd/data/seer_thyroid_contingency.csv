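histology,stage,group,count
follicular,I,1,3668
follicular,I,2,3
follicular,I,3,25
follicular,I,4,0
follicular,I,5,0
follicular,I,6,0
follicular,I,7,0
follicular,II,1,5
follicular,II,2,659
follicular,II,3,15
follicular,II,4,0
follicular,II,5,2
follicular,II,6,0
follicular,II,7,0
follicular,III,1,0
follicular,III,2,0
follicular,III,3,0
follicular,III,4,33
follicular,III,5,2
follicular,III,6,0
follicular,III,7,0
follicular,IVA,1,0
follicular,IVA,2,0
follicular,IVA,3,0
follicular,IVA,4,0
follicular,IVA,5,42
follicular,IVA,6,7
follicular,IVA,7,0
follicular,IVB,1,0
follicular,IVB,2,0
follicular,IVB,3,0
follicular,IVB,4,0
follicular,IVB,5,16
follicular,IVB,6,67
follicular,IVB,7,13
papillary,I,1,41634
papillary,I,2,463
papillary,I,3,180
papillary,I,4,0
papillary,I,5,0
papillary,I,6,0
papillary,I,7,0
papillary,II,1,436
papillary,II,2,2569
papillary,II,3,461
papillary,II,4,0
papillary,II,5,30
papillary,II,6,0
papillary,II,7,0
papillary,III,1,0
papillary,III,2,0
papillary,III,3,0
papillary,III,4,388
papillary,III,5,128
papillary,III,6,0
papillary,III,7,0
papillary,IVA,1,0
papillary,IVA,2,0
papillary,IVA,3,0
papillary,IVA,4,0
papillary,IVA,5,192
papillary,IVA,6,89
papillary,IVA,7,0
papillary,IVB,1,0
papillary,IVB,2,0
papillary,IVB,3,0
papillary,IVB,4,0
papillary,IVB,5,19
papillary,IVB,6,118
papillary,IVB,7,27
pooled,I,1,45302
pooled,I,2,466
pooled,I,3,205
pooled,I,4,0
pooled,I,5,0
pooled,I,6,0
pooled,I,7,0
pooled,II,1,441
pooled,II,2,3228
pooled,II,3,476
pooled,II,4,0
pooled,II,5,32
pooled,II,6,0
pooled,II,7,0
pooled,III,1,0
pooled,III,2,0
pooled,III,3,0
pooled,III,4,421
pooled,III,5,130
pooled,III,6,0
pooled,III,7,0
pooled,IVA,1,0
pooled,IVA,2,0
pooled,IVA,3,0
pooled,IVA,4,0
pooled,IVA,5,234
pooled,IVA,6,96
pooled,IVA,7,0
pooled,IVB,1,0
pooled,IVB,2,0
pooled,IVB,3,0
pooled,IVB,4,0
pooled,IVB,5,35
pooled,IVB,6,185
pooled,IVB,7,40
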