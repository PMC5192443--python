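substance,formula,isotope,mass,rel_intensity
aspartic acid,C4H7NO4,0,133.037508,100.00
aspartic acid,C4H7NO4,1,134.040468,4.96
aspartic acid,C4H7NO4,2,135.041918,0.93
aspartic acid,C4H7NO4,3,136.044728,0.04
cysteine,C3H7NO2S,0,121.019749,100.00
cysteine,C3H7NO2S,1,122.021976,4.59
cysteine,C3H7NO2S,2,123.016385,5.05
cysteine,C3H7NO2S,3,124.019165,0.19
cysteine,C3H7NO2S,4,125.018404,0.03
chloramphenicol,C11H12Cl2N2O5,0,322.012327,100.00
chloramphenicol,C11H12Cl2N2O5,1,323.015369,13.00
chloramphenicol,C11H12Cl2N2O5,2,324.009595,66.20
chloramphenicol,C11H12Cl2N2O5,3,325.012562,8.53
chloramphenicol,C11H12Cl2N2O5,4,326.007250,11.54
chloramphenicol,C11H12Cl2N2O5,5,327.010016,1.45
digoxigenin monodigitoxoside,C29H44O8,0,520.303618,100.00
digoxigenin monodigitoxoside,C29H44O8,1,521.307027,32.24
digoxigenin monodigitoxoside,C29H44O8,2,522.309803,6.70
digoxigenin monodigitoxoside,C29H44O8,3,523.312531,1.04
digoxigenin monodigitoxoside,C29H44O8,4,524.315166,0.13
digoxigenin monodigitoxoside,C29H44O8,5,525.317742,0.01
2-chloro-2'-deoxyadenosine-5'-triphosphate,C10H15ClN5O12P3,0,524.961858,100.00
2-chloro-2'-deoxyadenosine-5'-triphosphate,C10H15ClN5O12P3,1,525.964411,13.30
2-chloro-2'-deoxyadenosine-5'-triphosphate,C10H15ClN5O12P3,2,526.959596,35.41
2-chloro-2'-deoxyadenosine-5'-triphosphate,C10H15ClN5O12P3,3,527.962023,4.63
2-chloro-2'-deoxyadenosine-5'-triphosphate,C10H15ClN5O12P3,4,528.963673,1.11
2-chloro-2'-deoxyadenosine-5'-triphosphate,C10H15ClN5O12P3,5,529.966017,0.12
autoinducer-2,C5H10BO7,0,192.055590,24.37
autoinducer-2,C5H10BO7,1,193.052059,100.00
autoinducer-2,C5H10BO7,2,194.055706,6.13
autoinducer-2,C5H10BO7,3,195.056530,1.59
autoinducer-2,C5H10BO7,4,196.059851,0.09
autoinducer-2,C5H10BO7,5,197.060963,0.01
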