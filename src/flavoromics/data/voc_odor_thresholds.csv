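analyte,threshold,descriptor
(Z)-4-Heptenal,0.0034,Grassy-like
Alpha-pinene,1.0138,Pinewood-like
1-Butanol,10,Fruity-like
3-Methyl-1-butanol,0.3,Burnt malt-like
1-Hexanal-D,0.0075,Fresh apple-like
1-Hexanal-M,0.0075,Fresh apple-like
1-Nonanal-D,0.015,Fatty-like
1-Nonanal-M,0.015,Fatty-like
1-Octanal-D,0.0007,Orange-like
1-Octanal-M,0.0007,Orange-like
1-Octen-3-ol-D,0.007,Mushroom-like
1-Octen-3-ol-M,0.007,Mushroom-like
1-Octen-3-one-D,0.03,Mushroom-like
1-Octen-3-one-M,0.03,Mushroom-like
1-Pentanol,5,"Flowers-like, fruity-like"
2-Butanone-D,3,Pleasant fruity-like
2-Butanone-M,3,Pleasant fruity-like
2-Heptanone-D,0.2,"Blue cheese-like, nutty-like"
2-Heptanone-M,0.2,"Blue cheese-like, nutty-like"
2-Hexanol,6.7,
2-Hexanone,0.09,Pungent alcohol-like
2-Methylbutanal-D,0.003,"Almond-like, malt-like"
2-Methylbutanal-M,0.003,"Almond-like, malt-like"
2-Methylpyrazine,0.25,Hazelnut-like
2-Pentanone,0.09,Pungent alcohol-like
3-Methylbutanal,0.008,Apple-like
3-Octanol-D,0.1,Mushroom-like
3-Octanol-M,0.1,Mushroom-like
3-Octanone-D,1,Vanilla-like
3-Octanone-M,1,Vanilla-like
Ethyl acetate,0.1,Brandy-like
Butanal-D,0.00526,Banana-like
Butanal-M,0.00526,Banana-like
Ethyl formate,6.6,Pungent
Heptanal,0.01,Fatty-like
Methyl isovalerate,0.0004,Fruity-like
n-Pentanal-D,0.008,"Almond-like, malt-like"
n-Pentanal-M,0.008,"Almond-like, malt-like"
(E)-2-Octenal,,
2-Hexenal,,
2-Methyl-2-propenal,,
Propanal,,
(Z)-3-Hexen-1-ol butanoate,,
3-(Methylthio)-1-propene,,
Beta-ocimene,,
1-Octene,,
Camphene,,
Pyrrolidine,,
Tetrahydrofuran,,
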