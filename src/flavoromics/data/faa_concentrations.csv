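analyte,group,value,sd
Asp,A,242.34,0.06
Asp,B,226.52,0.22
Asp,C,212.64,0.21
Asp,D,232.73,0.01
Asp,E,257.52,0.10
Thr,A,215.30,0.32
Thr,B,215.75,0.08
Thr,C,214.12,0.02
Thr,D,211.40,0.53
Thr,E,233.52,0.51
Ser,A,197.50,0.42
Ser,B,192.27,0.14
Ser,C,189.11,0.20
Ser,D,191.11,0.26
Ser,E,212.81,0.01
Glu,A,1226.62,0.08
Glu,B,1174.41,0.05
Glu,C,1142.34,0.11
Glu,D,1191.36,0.33
Glu,E,1287.13,0.02
Gly,A,97.53,0.38
Gly,B,82.81,0.15
Gly,C,83.75,0.14
Gly,D,84.21,0.09
Gly,E,85.14,0.05
Ala,A,431.53,0.09
Ala,B,446.36,0.15
Ala,C,439.93,0.09
Ala,D,426.52,0.11
Ala,E,462.74,0.08
Cys,A,33.40,0.07
Cys,B,39.60,0.08
Cys,C,31.95,0.06
Cys,D,34.74,0.04
Cys,E,31.64,0.10
Val,A,152.54,0.10
Val,B,160.51,0.10
Val,C,153.31,0.01
Val,D,147.08,0.03
Val,E,168.51,0.03
Met,A,34.76,0.07
Met,B,36.23,0.22
Met,C,32.28,0.04
Met,D,24.03,0.02
Met,E,33.81,0.03
Ile,A,98.75,0.10
Ile,B,99.42,0.13
Ile,C,147.21,0.02
Ile,D,99.42,0.01
Ile,E,111.13,0.11
Leu,A,168.65,0.01
Leu,B,181.20,0.01
Leu,C,167.46,0.03
Leu,D,168.62,0.01
Leu,E,189.15,0.04
Tyr,A,79.32,0.59
Tyr,B,89.30,0.08
Tyr,C,82.45,0.04
Tyr,D,83.52,0.01
Tyr,E,79.82,0.02
Phe,A,106.54,0.06
Phe,B,107.43,0.06
Phe,C,98.36,0.04
Phe,D,101.82,0.01
Phe,E,111.20,0.02
His,A,253.10,0.18
His,B,264.10,0.07
His,C,273.72,0.07
His,D,326.12,0.01
His,E,313.87,0.04
Lys,A,137.72,0.01
Lys,B,139.53,0.06
Lys,C,131.53,0.03
Lys,D,128.81,0.03
Lys,E,152.41,0.01
Arg,A,469.64,0.05
Arg,B,406.23,0.05
Arg,C,369.12,0.04
Arg,D,378.05,0.24
Arg,E,528.12,0.03
Pro,A,94.37,0.05
Pro,B,95.11,0.09
Pro,C,95.12,0.02
Pro,D,91.21,0.09
Pro,E,99.13,0.02
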