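phenotype,analyte,target_ugL,provenance
EM,TAM,120.000000,assumed anchor
EM,NDM,250.000000,assumed anchor
EM,4OH,3.800000,reported reference median
EM,END,21.814156,lognormal quantile algebra from reported p5/p25
IM,TAM,132.000000,assumed ratio 1.1 x EM
IM,NDM,300.000000,assumed ratio 1.2 x EM
IM,4OH,2.500000,chosen inside EM band at doubled dose
IM,END,15.899437,EM median minus one unit endoxifen exposure
PM,TAM,168.000000,assumed ratio 1.4 x EM
PM,NDM,375.000000,assumed ratio 1.5 x EM
PM,4OH,2.250000,half the reported 40 mg q.d. median
PM,END,4.070000,half the reported 40 mg q.d. median
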