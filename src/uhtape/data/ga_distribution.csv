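site,ga_band,count
Argentina,20.0-23.6,39
Argentina,24.0-27.6,35
Argentina,28.0-31.6,39
Argentina,32.0-35.6,64
Argentina,36.0-40.6,107
Zambia,20.0-23.6,34
Zambia,24.0-27.6,25
Zambia,28.0-31.6,28
Zambia,32.0-35.6,63
Zambia,36.0-40.6,92
India,20.0-23.6,46
India,24.0-27.6,14
India,28.0-31.6,24
India,32.0-35.6,55
India,36.0-40.6,114
Pakistan,20.0-23.6,48
Pakistan,24.0-27.6,12
Pakistan,28.0-31.6,23
Pakistan,32.0-35.6,67
Pakistan,36.0-40.6,100
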