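analyte,chemical_class
(E)-2-Octenal,aldehyde
(Z)-4-Heptenal,aldehyde
1-Hexanal,aldehyde
1-Nonanal,aldehyde
1-Octanal,aldehyde
2-Hexenal,aldehyde
2-Methylbutanal,aldehyde
2-Methyl-2-propenal,aldehyde
3-Methylbutanal,aldehyde
Butanal,aldehyde
Heptanal,aldehyde
n-Pentanal,aldehyde
Propanal,aldehyde
1-Octen-3-one,ketone
2-Butanone,ketone
2-Heptanone,ketone
2-Hexanone,ketone
2-Pentanone,ketone
3-Octanone,ketone
1-Butanol,alcohol
3-Methyl-1-butanol,alcohol
1-Octen-3-ol,alcohol
1-Pentanol,alcohol
2-Hexanol,alcohol
3-Octanol,alcohol
(Z)-3-Hexen-1-ol butanoate,ester
Ethyl acetate,ester
Ethyl formate,ester
Methyl isovalerate,ester
3-(Methylthio)-1-propene,ether
Alpha-pinene,olefin
Beta-ocimene,olefin
1-Octene,olefin
Camphene,olefin
2-Methylpyrazine,heterocyclic
Pyrrolidine,heterocyclic
Tetrahydrofuran,heterocyclic
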