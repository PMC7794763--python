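variable,units,factor_a,factor_b,mean,sem,n
body_weight_3mo,g,nondiabetic,vehicle,23.0,1.2,10
body_weight_3mo,g,nondiabetic,fenofibrate,24.8,1.4,8
body_weight_3mo,g,diabetic,vehicle,49.7,1.1,10
body_weight_3mo,g,diabetic,fenofibrate,51.2,2.1,10
body_weight_6mo,g,nondiabetic,vehicle,28.3,1.3,10
body_weight_6mo,g,nondiabetic,fenofibrate,25.5,0.7,8
body_weight_6mo,g,diabetic,vehicle,57.0,2.4,10
body_weight_6mo,g,diabetic,fenofibrate,62.6,0.9,10
plasma_glucose_3mo,mg/dL,nondiabetic,vehicle,121.0,6.8,10
plasma_glucose_3mo,mg/dL,nondiabetic,fenofibrate,121.8,8.8,8
plasma_glucose_3mo,mg/dL,diabetic,vehicle,421.4,29.9,10
plasma_glucose_3mo,mg/dL,diabetic,fenofibrate,445.3,28.1,10
plasma_glucose_6mo,mg/dL,nondiabetic,vehicle,208.8,9.1,10
plasma_glucose_6mo,mg/dL,nondiabetic,fenofibrate,179.5,8.1,8
plasma_glucose_6mo,mg/dL,diabetic,vehicle,536.2,33.8,10
plasma_glucose_6mo,mg/dL,diabetic,fenofibrate,540.1,32.9,10
plasma_triglycerides_6mo,mg/dL,nondiabetic,vehicle,46.0,1.4,10
plasma_triglycerides_6mo,mg/dL,nondiabetic,fenofibrate,55.3,5.1,8
plasma_triglycerides_6mo,mg/dL,diabetic,vehicle,71.7,4.5,10
plasma_triglycerides_6mo,mg/dL,diabetic,fenofibrate,49.2,2.2,10
plasma_ffa_6mo,mM,nondiabetic,vehicle,0.81,0.04,10
plasma_ffa_6mo,mM,nondiabetic,fenofibrate,1.06,0.09,8
plasma_ffa_6mo,mM,diabetic,vehicle,1.46,0.04,10
plasma_ffa_6mo,mM,diabetic,fenofibrate,1.34,0.07,10
plasma_cholesterol_6mo,mg/dL,nondiabetic,vehicle,49.6,1.6,10
plasma_cholesterol_6mo,mg/dL,nondiabetic,fenofibrate,84.2,5.7,8
plasma_cholesterol_6mo,mg/dL,diabetic,vehicle,103.2,5.9,10
plasma_cholesterol_6mo,mg/dL,diabetic,fenofibrate,127.6,9.0,10
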