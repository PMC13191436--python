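analyte,group,value,sd
(E)-2-Octenal-D,A,1.30,0.11
(E)-2-Octenal-D,B,1.26,0.08
(E)-2-Octenal-D,C,1.21,0.07
(E)-2-Octenal-D,D,1.09,0.09
(E)-2-Octenal-D,E,0.88,0.06
(E)-2-Octenal-M,A,4.34,0.01
(E)-2-Octenal-M,B,4.18,0.01
(E)-2-Octenal-M,C,4.40,0.01
(E)-2-Octenal-M,D,4.22,0.01
(E)-2-Octenal-M,E,3.97,0.06
(Z)-4-Heptenal,A,0.67,0.05
(Z)-4-Heptenal,B,0.47,0.01
(Z)-4-Heptenal,C,0.38,0.04
(Z)-4-Heptenal,D,0.37,0.04
(Z)-4-Heptenal,E,0.30,0.04
1-Hexanal-D,A,1.08,0.01
1-Hexanal-D,B,1.69,0.01
1-Hexanal-D,C,1.77,0.01
1-Hexanal-D,D,1.94,0.05
1-Hexanal-D,E,1.76,0.03
1-Hexanal-M,A,1.08,0.02
1-Hexanal-M,B,1.21,0.00
1-Hexanal-M,C,1.32,0.03
1-Hexanal-M,D,1.23,0.01
1-Hexanal-M,E,1.33,0.02
1-Nonanal-D,A,2.28,0.01
1-Nonanal-D,B,3.58,0.08
1-Nonanal-D,C,2.99,0.03
1-Nonanal-D,D,3.69,0.07
1-Nonanal-D,E,2.58,0.06
1-Nonanal-M,A,5.04,0.12
1-Nonanal-M,B,6.58,0.09
1-Nonanal-M,C,5.87,0.16
1-Nonanal-M,D,5.93,0.67
1-Nonanal-M,E,5.65,0.71
1-Octanal-D,A,1.30,0.10
1-Octanal-D,B,1.43,0.09
1-Octanal-D,C,1.18,0.10
1-Octanal-D,D,1.88,0.04
1-Octanal-D,E,1.30,0.09
1-Octanal-M,A,2.39,0.09
1-Octanal-M,B,2.56,0.01
1-Octanal-M,C,2.44,0.09
1-Octanal-M,D,2.65,0.04
1-Octanal-M,E,2.62,0.16
2-Hexenal,A,0.21,0.01
2-Hexenal,B,0.24,0.01
2-Hexenal,C,0.25,0.02
2-Hexenal,D,0.29,0.04
2-Hexenal,E,0.29,0.03
2-Methylbutanal-D,A,1.93,0.07
2-Methylbutanal-D,B,1.79,0.01
2-Methylbutanal-D,C,1.79,0.01
2-Methylbutanal-D,D,1.88,0.06
2-Methylbutanal-D,E,1.68,0.06
2-Methyl-2-propenal,A,0.10,0.01
2-Methyl-2-propenal,B,0.12,0.01
2-Methyl-2-propenal,C,0.13,0.01
2-Methyl-2-propenal,D,0.13,0.03
2-Methyl-2-propenal,E,0.15,0.02
2-Methylbutanal-M,A,0.17,0.01
2-Methylbutanal-M,B,0.13,0.01
2-Methylbutanal-M,C,0.15,0.01
2-Methylbutanal-M,D,0.12,0.02
2-Methylbutanal-M,E,0.14,0.01
3-Methylbutanal,A,0.08,0.00
3-Methylbutanal,B,0.10,0.00
3-Methylbutanal,C,0.11,0.01
3-Methylbutanal,D,0.14,0.02
3-Methylbutanal,E,0.14,0.01
Butanal-D,A,0.11,0.00
Butanal-D,B,0.11,0.00
Butanal-D,C,0.09,0.00
Butanal-D,D,0.10,0.00
Butanal-D,E,0.10,0.00
Butanal-M,A,3.01,0.28
Butanal-M,B,3.10,0.10
Butanal-M,C,3.45,0.23
Butanal-M,D,3.48,0.36
Butanal-M,E,3.85,0.37
Heptanal,A,1.35,0.01
Heptanal,B,1.49,0.00
Heptanal,C,1.33,0.01
Heptanal,D,1.46,0.01
Heptanal,E,1.43,0.00
n-Pentanal-D,A,1.63,0.00
n-Pentanal-D,B,1.76,0.00
n-Pentanal-D,C,1.65,0.04
n-Pentanal-D,D,1.85,0.04
n-Pentanal-D,E,1.67,0.02
n-Pentanal-M,A,0.50,0.06
n-Pentanal-M,B,0.48,0.03
n-Pentanal-M,C,0.53,0.06
n-Pentanal-M,D,0.53,0.09
n-Pentanal-M,E,0.63,0.09
Propanal,A,0.35,0.03
Propanal,B,0.38,0.01
Propanal,C,0.42,0.03
Propanal,D,0.27,0.03
Propanal,E,0.37,0.04
1-Octen-3-one-D,A,20.06,1.89
1-Octen-3-one-D,B,17.82,0.53
1-Octen-3-one-D,C,17.28,0.94
1-Octen-3-one-D,D,16.52,1.69
1-Octen-3-one-D,E,16.23,1.52
1-Octen-3-one-M,A,5.72,0.20
1-Octen-3-one-M,B,5.59,0.08
1-Octen-3-one-M,C,5.72,0.09
1-Octen-3-one-M,D,5.32,0.27
1-Octen-3-one-M,E,5.75,0.11
2-Butanone-D,A,0.32,0.03
2-Butanone-D,B,0.39,0.05
2-Butanone-D,C,0.52,0.06
2-Butanone-D,D,0.34,0.07
2-Butanone-D,E,0.42,0.10
2-Butanone-M,A,0.18,0.01
2-Butanone-M,B,0.18,0.01
2-Butanone-M,C,0.20,0.00
2-Butanone-M,D,0.17,0.00
2-Butanone-M,E,0.19,0.00
2-Heptanone-D,A,0.70,0.05
2-Heptanone-D,B,0.95,0.04
2-Heptanone-D,C,1.10,0.09
2-Heptanone-D,D,1.30,0.13
2-Heptanone-D,E,1.43,0.13
2-Heptanone-M,A,1.35,0.03
2-Heptanone-M,B,1.45,0.01
2-Heptanone-M,C,2.06,0.66
2-Heptanone-M,D,1.70,0.08
2-Heptanone-M,E,1.93,0.08
2-Hexanone,A,1.31,0.04
2-Hexanone,B,1.20,0.05
2-Hexanone,C,1.31,0.04
2-Hexanone,D,1.25,0.00
2-Hexanone,E,1.38,0.02
2-Pentanone,A,0.66,0.11
2-Pentanone,B,0.67,0.03
2-Pentanone,C,0.86,0.07
2-Pentanone,D,0.61,0.06
2-Pentanone,E,0.76,0.04
3-Octanone-D,A,2.19,0.10
3-Octanone-D,B,1.93,0.03
3-Octanone-D,C,1.35,0.03
3-Octanone-D,D,1.40,0.01
3-Octanone-D,E,2.14,0.18
3-Octanone-M,A,3.77,0.03
3-Octanone-M,B,3.44,0.01
3-Octanone-M,C,2.97,0.12
3-Octanone-M,D,3.02,0.07
3-Octanone-M,E,3.60,0.14
1-Butanol,A,0.22,0.02
1-Butanol,B,0.27,0.00
1-Butanol,C,0.27,0.02
1-Butanol,D,0.29,0.03
1-Butanol,E,0.31,0.02
3-Methyl-1-butanol,A,0.47,0.01
3-Methyl-1-butanol,B,0.49,0.00
3-Methyl-1-butanol,C,0.45,0.00
3-Methyl-1-butanol,D,0.50,0.01
3-Methyl-1-butanol,E,0.51,0.00
1-Octen-3-ol-D,A,5.57,0.45
1-Octen-3-ol-D,B,5.11,0.19
1-Octen-3-ol-D,C,5.54,0.35
1-Octen-3-ol-D,D,4.61,0.44
1-Octen-3-ol-D,E,4.06,0.35
1-Octen-3-ol-M,A,11.16,0.02
1-Octen-3-ol-M,B,10.59,0.19
1-Octen-3-ol-M,C,11.39,0.09
1-Octen-3-ol-M,D,10.85,0.22
1-Octen-3-ol-M,E,10.89,0.10
1-Pentanol,A,0.29,0.04
1-Pentanol,B,0.34,0.01
1-Pentanol,C,0.36,0.02
1-Pentanol,D,0.42,0.05
1-Pentanol,E,0.38,0.11
2-Hexanol,A,0.93,0.14
2-Hexanol,B,0.95,0.04
2-Hexanol,C,1.11,0.12
2-Hexanol,D,1.10,0.18
2-Hexanol,E,1.28,0.16
3-Octanol-D,A,0.33,0.06
3-Octanol-D,B,0.24,0.02
3-Octanol-D,C,0.25,0.02
3-Octanol-D,D,0.24,0.05
3-Octanol-D,E,0.21,0.03
3-Octanol-M,A,0.63,0.08
3-Octanol-M,B,0.58,0.01
3-Octanol-M,C,0.61,0.04
3-Octanol-M,D,0.54,0.04
3-Octanol-M,E,0.55,0.03
(Z)-3-Hexen-1-ol butanoate,A,0.50,0.03
(Z)-3-Hexen-1-ol butanoate,B,0.65,0.03
(Z)-3-Hexen-1-ol butanoate,C,0.56,0.06
(Z)-3-Hexen-1-ol butanoate,D,0.65,0.06
(Z)-3-Hexen-1-ol butanoate,E,0.63,0.08
Ethyl acetate,A,0.35,0.04
Ethyl acetate,B,0.40,0.01
Ethyl acetate,C,0.46,0.02
Ethyl acetate,D,0.47,0.05
Ethyl acetate,E,0.54,0.04
Ethyl formate,A,0.29,0.04
Ethyl formate,B,0.33,0.01
Ethyl formate,C,0.40,0.03
Ethyl formate,D,0.38,0.04
Ethyl formate,E,0.39,0.09
Methyl isovalerate,A,0.26,0.01
Methyl isovalerate,B,0.26,0.02
Methyl isovalerate,C,0.26,0.02
Methyl isovalerate,D,0.29,0.01
Methyl isovalerate,E,0.32,0.03
3-(Methylthio)-1-propene,A,0.73,0.08
3-(Methylthio)-1-propene,B,0.63,0.04
3-(Methylthio)-1-propene,C,0.73,0.05
3-(Methylthio)-1-propene,D,0.65,0.06
3-(Methylthio)-1-propene,E,0.71,0.06
Alpha-pinene,A,0.30,0.02
Alpha-pinene,B,0.28,0.00
Alpha-pinene,C,0.24,0.01
Alpha-pinene,D,0.23,0.01
Alpha-pinene,E,0.20,0.01
Beta-ocimene,A,0.25,0.05
Beta-ocimene,B,0.32,0.04
Beta-ocimene,C,0.36,0.04
Beta-ocimene,D,0.45,0.09
Beta-ocimene,E,0.42,0.10
1-Octene,A,0.12,0.03
1-Octene,B,0.12,0.02
1-Octene,C,0.11,0.01
1-Octene,D,0.15,0.01
1-Octene,E,0.16,0.03
Camphene,A,0.08,0.01
Camphene,B,0.10,0.00
Camphene,C,0.11,0.01
Camphene,D,0.13,0.01
Camphene,E,0.16,0.02
2-Methylpyrazine,A,0.14,0.02
2-Methylpyrazine,B,0.10,0.00
2-Methylpyrazine,C,0.10,0.01
2-Methylpyrazine,D,0.09,0.01
2-Methylpyrazine,E,0.10,0.00
Pyrrolidine,A,0.39,0.05
Pyrrolidine,B,0.42,0.01
Pyrrolidine,C,0.50,0.03
Pyrrolidine,D,0.41,0.05
Pyrrolidine,E,0.49,0.05
Tetrahydrofuran,A,1.28,0.02
Tetrahydrofuran,B,1.20,0.01
Tetrahydrofuran,C,1.18,0.01
Tetrahydrofuran,D,1.19,0.01
Tetrahydrofuran,E,1.20,0.01
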