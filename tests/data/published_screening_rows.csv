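sex,index,cutoff_level,auc,sensitivity_pct,specificity_pct,youden,auc_discrepant
female,bri,p75,0.693,61.8,76.8,0.386,0
female,bri,p85,0.678,50.7,85.0,0.357,0
female,bri,p95,0.641,35.0,93.3,0.283,0
female,whr,p75,0.619,43.8,80.0,0.238,0
female,whr,p85,0.598,28.9,90.8,0.197,0
female,whr,p95,0.549,11.5,98.3,0.098,0
female,whtr,p75,0.686,51.3,85.8,0.371,0
female,whtr,p85,0.646,34.2,95.1,0.293,0
female,whtr,p95,0.549,13.3,99.7,0.130,1
female,bmi,p75,0.651,35.2,94.9,0.301,0
female,bmi,p85,0.642,32.1,96.3,0.284,0
female,bmi,p95,0.558,11.7,99.8,0.115,0
male,bri,p75,0.752,71.3,79.1,0.504,0
male,bri,p85,0.750,62.9,87.1,0.500,0
male,bri,p95,0.714,48.4,94.4,0.428,0
male,whr,p75,0.656,45.0,86.2,0.312,0
male,whr,p85,0.617,29.9,93.6,0.235,0
male,whr,p95,0.551,11.7,98.5,0.102,0
male,whtr,p75,0.725,53.2,91.7,0.449,0
male,whtr,p85,0.666,35.8,97.4,0.332,0
male,whtr,p95,0.566,13.4,99.9,0.133,0
male,bmi,p75,0.733,57.3,89.4,0.466,0
male,bmi,p85,0.655,32.8,98.3,0.311,0
male,bmi,p95,0.555,11.1,99.9,0.110,0
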