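site,endpoint,auc
Argentina,24.0-35.6,0.64
Zambia,24.0-35.6,0.65
India,24.0-35.6,0.71
Pakistan,24.0-35.6,0.72
Argentina,20.0-35.6,0.69
Zambia,20.0-35.6,0.72
India,20.0-35.6,0.84
Pakistan,20.0-35.6,0.83
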