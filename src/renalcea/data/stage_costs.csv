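stage,cost_diabetic,cost_nondiabetic,prop_diabetic,stage_weight
1,420,412,0.51,0.18
2,420,412,0.42,0.25
3a,476,464,0.29,0.41
3b,867,691,0.24,0.11
4,1736,1456,0.22,0.05
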