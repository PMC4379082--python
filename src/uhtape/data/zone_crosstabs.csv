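site,tape,zone,ga_band,count
Argentina,10-90,low,20.0-23.6,10
Argentina,10-90,low,24.0-35.6,2
Argentina,10-90,low,36.0-40.6,0
Argentina,10-90,mid,20.0-23.6,29
Argentina,10-90,mid,24.0-35.6,126
Argentina,10-90,mid,36.0-40.6,75
Argentina,10-90,high,20.0-23.6,0
Argentina,10-90,high,24.0-35.6,10
Argentina,10-90,high,36.0-40.6,32
Argentina,50-50,low,20.0-23.6,16
Argentina,50-50,low,24.0-35.6,11
Argentina,50-50,low,36.0-40.6,1
Argentina,50-50,mid,20.0-23.6,23
Argentina,50-50,mid,24.0-35.6,113
Argentina,50-50,mid,36.0-40.6,73
Argentina,50-50,high,20.0-23.6,0
Argentina,50-50,high,24.0-35.6,14
Argentina,50-50,high,36.0-40.6,32
Argentina,90-10,low,20.0-23.6,24
Argentina,90-10,low,24.0-35.6,18
Argentina,90-10,low,36.0-40.6,2
Argentina,90-10,mid,20.0-23.6,15
Argentina,90-10,mid,24.0-35.6,97
Argentina,90-10,mid,36.0-40.6,50
Argentina,90-10,high,20.0-23.6,0
Argentina,90-10,high,24.0-35.6,23
Argentina,90-10,high,36.0-40.6,55
Zambia,10-90,low,20.0-23.6,28
Zambia,10-90,low,24.0-35.6,14
Zambia,10-90,low,36.0-40.6,0
Zambia,10-90,mid,20.0-23.6,6
Zambia,10-90,mid,24.0-35.6,92
Zambia,10-90,mid,36.0-40.6,64
Zambia,10-90,high,20.0-23.6,0
Zambia,10-90,high,24.0-35.6,10
Zambia,10-90,high,36.0-40.6,28
Zambia,50-50,low,20.0-23.6,30
Zambia,50-50,low,24.0-35.6,25
Zambia,50-50,low,36.0-40.6,0
Zambia,50-50,mid,20.0-23.6,4
Zambia,50-50,mid,24.0-35.6,82
Zambia,50-50,mid,36.0-40.6,57
Zambia,50-50,high,20.0-23.6,0
Zambia,50-50,high,24.0-35.6,9
Zambia,50-50,high,36.0-40.6,35
Zambia,90-10,low,20.0-23.6,33
Zambia,90-10,low,24.0-35.6,35
Zambia,90-10,low,36.0-40.6,2
Zambia,90-10,mid,20.0-23.6,1
Zambia,90-10,mid,24.0-35.6,67
Zambia,90-10,mid,36.0-40.6,44
Zambia,90-10,high,20.0-23.6,0
Zambia,90-10,high,24.0-35.6,14
Zambia,90-10,high,36.0-40.6,46
India,10-90,low,20.0-23.6,41
India,10-90,low,24.0-35.6,8
India,10-90,low,36.0-40.6,1
India,10-90,mid,20.0-23.6,5
India,10-90,mid,24.0-35.6,83
India,10-90,mid,36.0-40.6,108
India,10-90,high,20.0-23.6,0
India,10-90,high,24.0-35.6,2
India,10-90,high,36.0-40.6,5
India,50-50,low,20.0-23.6,45
India,50-50,low,24.0-35.6,18
India,50-50,low,36.0-40.6,1
India,50-50,mid,20.0-23.6,1
India,50-50,mid,24.0-35.6,71
India,50-50,mid,36.0-40.6,89
India,50-50,high,20.0-23.6,0
India,50-50,high,24.0-35.6,4
India,50-50,high,36.0-40.6,24
India,90-10,low,20.0-23.6,46
India,90-10,low,24.0-35.6,21
India,90-10,low,36.0-40.6,1
India,90-10,mid,20.0-23.6,0
India,90-10,mid,24.0-35.6,41
India,90-10,mid,36.0-40.6,12
India,90-10,high,20.0-23.6,0
India,90-10,high,24.0-35.6,31
India,90-10,high,36.0-40.6,101
Pakistan,10-90,low,20.0-23.6,12
Pakistan,10-90,low,24.0-35.6,0
Pakistan,10-90,low,36.0-40.6,0
Pakistan,10-90,mid,20.0-23.6,36
Pakistan,10-90,mid,24.0-35.6,95
Pakistan,10-90,mid,36.0-40.6,80
Pakistan,10-90,high,20.0-23.6,0
Pakistan,10-90,high,24.0-35.6,7
Pakistan,10-90,high,36.0-40.6,20
Pakistan,50-50,low,20.0-23.6,33
Pakistan,50-50,low,24.0-35.6,7
Pakistan,50-50,low,36.0-40.6,0
Pakistan,50-50,mid,20.0-23.6,15
Pakistan,50-50,mid,24.0-35.6,78
Pakistan,50-50,mid,36.0-40.6,49
Pakistan,50-50,high,20.0-23.6,0
Pakistan,50-50,high,24.0-35.6,17
Pakistan,50-50,high,36.0-40.6,51
Pakistan,90-10,low,20.0-23.6,42
Pakistan,90-10,low,24.0-35.6,12
Pakistan,90-10,low,36.0-40.6,0
Pakistan,90-10,mid,20.0-23.6,5
Pakistan,90-10,mid,24.0-35.6,35
Pakistan,90-10,mid,36.0-40.6,6
Pakistan,90-10,high,20.0-23.6,1
Pakistan,90-10,high,24.0-35.6,55
Pakistan,90-10,high,36.0-40.6,94
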