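participant,run1,run2,run3,run4,run5,run6,run7,run8,run9,run10,mean
P1,91.11,84.44,97.78,97.78,95.56,93.33,86.66,95.55,75.55,86.66,90.44
P2,95.56,93.33,88.89,86.67,95.56,77.78,88.89,88.89,55.56,86.67,85.78
P3,88.89,88.89,95.56,77.78,66.67,97.78,86.67,88.89,93.33,88.89,87.34
P4,77.78,88.89,77.78,64.44,77.77,75.56,71.11,66.67,93.33,48.89,74.22
P5,82.22,84.44,80.00,86.67,88.89,91.11,86.67,82.22,97.78,82.22,86.22
P6,82.22,93.33,71.11,88.89,68.89,77.78,86.67,93.33,71.11,100.0,83.33
P7,82.22,95.56,93.33,91.11,86.67,97.78,95.56,97.78,84.44,97.78,93.33
P8,91.11,95.56,64.44,75.56,95.56,93.33,80.00,86.67,86.67,93.33,86.22
P9,82.22,75.56,71.11,73.33,84.44,88.89,62.22,95.56,86.67,88.89,80.89
P10,88.89,91.11,84.44,75.56,91.11,51.11,86.67,84.44,84.44,68.89,80.67
P11,91.11,75.56,91.11,95.56,80.00,71.11,82.22,82.22,73.33,66.67,80.89
P12,55.56,66.67,80.00,46.67,62.22,71.11,82.22,68.89,62.22,71.11,66.67
P13,80.00,62.22,60.00,77.78,73.33,75.56,75.56,77.78,93.33,60.00,73.56
P14,88.89,64.44,93.33,82.22,75.56,93.33,86.67,66.67,93.33,91.11,83.56
P15,66.67,60.00,55.56,64.44,84.44,60.00,55.56,48.89,66.67,71.11,63.33
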