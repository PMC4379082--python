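site,tape,endpoint,statistic,estimate_pct,ci_low_pct,ci_high_pct
Argentina,10-90,24.0-35.6,sensitivity,91.3,86.6,96.0
Argentina,10-90,24.0-35.6,specificity,28.8,21.4,36.1
Zambia,10-90,24.0-35.6,sensitivity,79.3,71.9,86.7
Zambia,10-90,24.0-35.6,specificity,44.4,35.8,53.1
India,10-90,24.0-35.6,sensitivity,89.2,83.0,95.5
India,10-90,24.0-35.6,specificity,29.4,22.3,36.4
Pakistan,10-90,24.0-35.6,sensitivity,93.1,88.2,98.0
Pakistan,10-90,24.0-35.6,specificity,21.6,15.0,28.3
Argentina,50-50,24.0-35.6,sensitivity,81.9,75.5,88.3
Argentina,50-50,24.0-35.6,specificity,33.8,26.1,41.5
Zambia,50-50,24.0-35.6,sensitivity,70.7,62.4,79.0
Zambia,50-50,24.0-35.6,specificity,51.6,42.9,60.3
India,50-50,24.0-35.6,sensitivity,76.3,67.7,85.0
India,50-50,24.0-35.6,specificity,43.8,36.1,51.4
Pakistan,50-50,24.0-35.6,sensitivity,76.5,68.2,84.7
Pakistan,50-50,24.0-35.6,specificity,56.8,48.8,64.7
Argentina,90-10,24.0-35.6,sensitivity,70.3,62.7,77.9
Argentina,90-10,24.0-35.6,specificity,55.5,47.4,63.5
Zambia,90-10,24.0-35.6,sensitivity,57.8,48.8,66.7
Zambia,90-10,24.0-35.6,specificity,64.3,55.9,72.7
India,90-10,24.0-35.6,sensitivity,44.1,34.0,54.2
India,90-10,24.0-35.6,specificity,92.5,88.4,96.6
Pakistan,90-10,24.0-35.6,sensitivity,34.3,25.1,43.5
Pakistan,90-10,24.0-35.6,specificity,92.6,88.3,96.8
Argentina,10-90,20.0-35.6,sensitivity,94.4,90.9,97.8
Argentina,10-90,20.0-35.6,specificity,29.9,21.2,38.6
Zambia,10-90,20.0-35.6,sensitivity,93.3,89.3,97.3
Zambia,10-90,20.0-35.6,specificity,30.4,21.0,39.8
India,10-90,20.0-35.6,sensitivity,98.6,96.6,100.5
India,10-90,20.0-35.6,specificity,4.4,0.6,8.1
Pakistan,10-90,20.0-35.6,sensitivity,95.3,92.0,98.7
Pakistan,10-90,20.0-35.6,specificity,20.0,12.2,27.8
Argentina,50-50,20.0-35.6,sensitivity,92.1,88.1,96.1
Argentina,50-50,20.0-35.6,specificity,30.2,21.4,38.9
Zambia,50-50,20.0-35.6,sensitivity,94.0,90.2,97.8
Zambia,50-50,20.0-35.6,specificity,38.0,28.1,48.0
India,50-50,20.0-35.6,sensitivity,97.1,94.3,99.9
India,50-50,20.0-35.6,specificity,21.1,13.6,28.5
Pakistan,50-50,20.0-35.6,sensitivity,88.7,83.6,93.7
Pakistan,50-50,20.0-35.6,specificity,51.0,41.2,60.8
Argentina,90-10,20.0-35.6,sensitivity,87.0,82.1,92.0
Argentina,90-10,20.0-35.6,specificity,51.4,41.9,60.9
Zambia,90-10,20.0-35.6,sensitivity,90.7,86.0,95.3
Zambia,90-10,20.0-35.6,specificity,50.0,39.8,60.2
India,90-10,20.0-35.6,sensitivity,77.7,70.8,84.6
India,90-10,20.0-35.6,specificity,88.6,82.8,94.4
Pakistan,90-10,20.0-35.6,sensitivity,62.7,54.9,70.4
Pakistan,90-10,20.0-35.6,specificity,94.0,89.3,98.7
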