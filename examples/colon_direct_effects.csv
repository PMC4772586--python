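equation,regressor,estimate,se
hazard,age10,0.299,0.036
hazard,affluence,-0.596,0.271
hazard,emergency,0.411,0.084
hazard,stage2,0.639,0.213
hazard,stage3,1.306,0.21
hazard,stage4,3.193,0.207
hazard,treatment,-0.766,0.106
hazard,caseload,-0.173,0.071
emergency,intercept,0.241,0.061
emergency,age10,0.023,0.007
emergency,affluence,-0.302,0.062
caseload,intercept,0.192,0.074
caseload,age10,-0.009,0.008
caseload,affluence,0.576,0.077
caseload,emergency,-0.063,0.023
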