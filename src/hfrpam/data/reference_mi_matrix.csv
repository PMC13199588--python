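code,X1,X2,X3,X4,X5,X6,X7,X8
X1,NA,0.0249,0.1648,0.1098,0.1098,0.1134,0.0057,0.0249
X2,0.0249,NA,0.2839,0.4798,0.2693,0.1304,0.1098,0.1844
X3,0.1648,0.2839,NA,0.0854,0.3174,0.0936,0.1514,0.2839
X4,0.1098,0.4798,0.0854,NA,0.4501,0.3688,0.2327,0.3652
X5,0.1098,0.2693,0.3174,0.4501,NA,0.3688,0.0964,0.7513
X6,0.1134,0.1304,0.0936,0.3688,0.3688,NA,0.145,0.5567
X7,0.0057,0.1098,0.1514,0.2327,0.0964,0.145,NA,0.1993
X8,0.0249,0.1844,0.2839,0.3652,0.7513,0.5567,0.1993,NA
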