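analyte,group,value,sd
5'-GMP,A,3.76,0.13
5'-GMP,B,4.26,0.20
5'-GMP,C,5.33,0.26
5'-GMP,D,5.46,0.13
5'-GMP,E,7.81,0.33
5'-AMP,A,0.35,0.01
5'-AMP,B,0.28,0.00
5'-AMP,C,0.27,0.04
5'-AMP,D,0.29,0.02
5'-AMP,E,0.27,0.02
5'-UMP,A,0.34,0.02
5'-UMP,B,0.43,0.03
5'-UMP,C,0.49,0.02
5'-UMP,D,0.39,0.01
5'-UMP,E,0.30,0.01
5'-CMP,A,6.54,0.02
5'-CMP,B,5.35,0.06
5'-CMP,C,5.67,0.01
5'-CMP,D,4.95,0.18
5'-CMP,E,6.42,0.32
5'-IMP,A,0.56,0.02
5'-IMP,B,0.36,0.01
5'-IMP,C,0.38,0.02
5'-IMP,D,0.34,0.05
5'-IMP,E,0.18,0.01
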