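code,weight_pct
X1,12.82
X2,12.48
X3,12.54
X4,12.52
X5,12.46
X6,12.46
X7,12.46
X8,12.25
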