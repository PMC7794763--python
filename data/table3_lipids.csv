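variable,units,factor_a,factor_b,mean,sem,n
liver_cholesterol_6mo,mg/dL/g,nondiabetic,vehicle,0.158,0.016,3
liver_cholesterol_6mo,mg/dL/g,nondiabetic,fenofibrate,0.15,0.005,3
liver_cholesterol_6mo,mg/dL/g,diabetic,vehicle,0.238,0.015,3
liver_cholesterol_6mo,mg/dL/g,diabetic,fenofibrate,0.255,0.017,3
retinal_cholesterol_6mo,mg/dL/g,nondiabetic,vehicle,0.123,0.004,3
retinal_cholesterol_6mo,mg/dL/g,nondiabetic,fenofibrate,0.145,0.013,3
retinal_cholesterol_6mo,mg/dL/g,diabetic,vehicle,0.137,0.006,3
retinal_cholesterol_6mo,mg/dL/g,diabetic,fenofibrate,0.127,0.012,3
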