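model,concentration_M,t_mid
gompertz,0.00,121.7
gompertz,0.15,119.8
gompertz,0.30,124.4
gompertz,0.45,140.2
gompertz,0.60,153.3
gompertz,0.75,159.6
gompertz,0.90,199.8
gompertz,1.05,215.7
gompertz,1.20,260.7
gompertz,1.35,275.0
gompertz,1.50,271.5
logit,0.00,123.5
logit,0.15,122.8
logit,0.30,130.2
logit,0.45,152.8
logit,0.60,165.8
logit,0.75,172.2
logit,0.90,207.7
logit,1.05,228.5
logit,1.20,266.5
logit,1.35,282.1
logit,1.50,277.7
dose_response,0.00,122.2
dose_response,0.15,120.3
dose_response,0.30,125.0
dose_response,0.45,140.9
dose_response,0.60,154.2
dose_response,0.75,160.5
dose_response,0.90,201.1
dose_response,1.05,217.0
dose_response,1.20,262.9
dose_response,1.35,276.7
dose_response,1.50,273.5
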