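model,concentration_M,s_dvp
gompertz,0.00,0.043
gompertz,0.15,0.036
gompertz,0.30,0.029
gompertz,0.45,0.023
gompertz,0.60,0.016
gompertz,0.75,0.016
gompertz,0.90,0.015
gompertz,1.05,0.014
gompertz,1.20,0.010
gompertz,1.35,0.014
gompertz,1.50,0.011
logit,0.00,0.106
logit,0.15,0.088
logit,0.30,0.073
logit,0.45,0.055
logit,0.60,0.038
logit,0.75,0.037
logit,0.90,0.052
logit,1.05,0.045
logit,1.20,0.040
logit,1.35,0.056
logit,1.50,0.044
dose_response,0.00,20.98
dose_response,0.15,16.91
dose_response,0.30,13.98
dose_response,0.45,12.27
dose_response,0.60,9.25
dose_response,0.75,10.12
dose_response,0.90,12.07
dose_response,1.05,11.45
dose_response,1.20,9.97
dose_response,1.35,14.94
dose_response,1.50,11.95
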