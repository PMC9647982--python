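hmdb_id,common_name,h2,se_h2,rg_fcr,se_rg_fcr,rg_rfi,se_rg_rfi,rp_fcr,se_rp_fcr,rp_rfi,se_rp_rfi
HMDB0031469,Asarone,0.59,0.13,-0.12,0.22,-0.01,0.19,-0.11,0.05,-0.11,0.06
HMDB0000225,2-Oxoadipic acid,0.58,0.13,0.44,0.20,0.46,0.17,0.12,0.05,0.19,0.06
HMDB0004089,2-(Formylamino)benzoic acid,0.54,0.13,-0.14,0.23,-0.25,0.20,-0.11,0.05,-0.16,0.06
HMDB0000670,L-Homoarginine,0.53,0.13,0.34,0.23,0.37,0.20,-0.03,0.06,0.09,0.06
HMDB0035906,(+)-Alantolactone,0.51,0.12,0.07,0.23,0.06,0.20,-0.04,0.05,-0.05,0.06
HMDB0033338,Mollicellin F,0.43,0.13,0.38,0.23,0.25,0.21,0.18,0.05,0.19,0.05
HMDB0002833,Testosterone,0.43,0.12,-0.58,0.20,-0.58,0.18,-0.22,0.05,-0.23,0.05
HMDB0000045,Adenosine 5'-monophosphate,0.42,0.12,0.51,0.23,0.30,0.20,0.18,0.05,0.18,0.05
HMDB0029467,Eugenitin,0.42,0.13,-0.02,0.26,-0.09,0.22,0.03,0.05,0,0.06
HMDB0000017,4-Pyridoxic acid,0.41,0.13,0.28,0.26,0.12,0.23,0.01,0.05,-0.04,0.06
HMDB0000531,3-Hydroxyvaleric acid,0.41,0.13,-0.23,0.26,0.18,0.23,0.07,0.05,0.11,0.06
HMDB0005814,Testate,0.38,0.12,-0.22,0.26,-0.09,0.23,0.02,0.05,0.01,0.06
HMDB0002226,Adrenic acid,0.37,0.12,-0.68,0.23,-0.38,0.21,-0.15,0.05,-0.17,0.05
HMDB0000575,DL-Homocystine,0.36,0.13,0.10,0.27,0.10,0.24,0.16,0.05,0.15,0.05
HMDB0062219,"(13Z,16Z)-Docosadienoic acid",0.33,0.12,-0.67,0.26,-0.42,0.23,-0.08,0.05,-0.11,0.05
HMDB0060029,"5-(3',4',5'-Trihydroxyphenyl)-gamma-valerolactone-O-methyl-O-sulphate",0.32,0.13,0.19,0.28,0.13,0.25,0.17,0.05,0.09,0.05
HMDB0003012,Aniline,0.28,0.11,-0.14,0.28,-0.31,0.24,-0.02,0.05,-0.08,0.05
HMDB0000634,Mesaconic acid,0.28,0.11,-0.09,0.29,0.22,0.26,-0.03,0.05,0.02,0.05
HMDB0000054,Bilirubin,0.28,0.10,-0.04,0.28,0.03,0.24,0,0.05,-0.01,0.05
HMDB0000308,3b-Hydroxy-5-cholenoic acid,0.24,0.12,0.39,0.31,0.66,0.28,0.03,0.05,0.06,0.05
HMDB0002032,8-Oxoguanine,0.24,0.12,-0.11,0.32,0.01,0.27,0,0.05,0.03,0.05
HMDB0000292,Xanthine,0.21,0.11,0.03,0.33,-0.12,0.28,-0.02,0.05,-0.06,0.05
HMDB0001903,Calcitriol,0.21,0.11,-0.38,0.32,-0.02,0.29,-0.05,0.05,-0.02,0.05
HMDB0039275,Gingerdione,0.19,0.10,-0.31,0.32,-0.31,0.28,-0.01,0.05,0.02,0.05
HMDB0000807,3-Phosphoglyceric acid,0.19,0.11,-0.39,0.35,-0.21,0.30,-0.02,0.05,0.03,0.05
HMDB0000044,L-Ascorbate,0.17,0.10,-0.58,0.31,-0.37,0.28,-0.08,0.05,-0.08,0.05
HMDB0000208,2-Oxoglutaric acid,0.17,0.11,-0.07,0.35,0.07,0.31,0.02,0.05,-0.01,0.05
HMDB0000812,N-Acetylaspartic acid,0.15,0.11,-0.78,0.37,-0.55,0.34,-0.04,0.05,-0.06,0.05
HMDB0001991,7-Methylxanthine,0.14,0.11,-0.19,0.40,0.51,0.33,-0.11,0.05,-0.06,0.05
HMDB0000786,Oxypurinol,0.12,0.11,-0.06,0.42,-0.28,0.35,-0.10,0.05,-0.14,0.05
HMDB0005998,"20-Hydroxy-(5Z,8Z,11Z,14Z)-eicosatetraenoic acid",0.12,0.09,-0.67,0.37,-0.58,0.33,-0.10,0.05,-0.13,0.05
HMDB0033704,Hexose,0.11,0.10,0.12,0.43,-0.04,0.38,0,0.05,0.02,0.05
HMDB0041610,Phenylacetaldehyde,0.10,0.10,-0.38,0.42,-0.23,0.38,-0.16,0.05,-0.12,0.05
HMDB0002580,Taurolithocholic acid sulfate,0.10,0.09,0.07,0.44,0.26,0.38,0.04,0.05,0.03,0.05
HMDB0015302,Aurorix,0.09,0.09,-0.06,0.44,0.31,0.39,-0.02,0.05,0.01,0.05
HMDB0000202,Methylmalonic acid,0.08,0.09,0.13,0.50,-0.45,0.40,0,0.05,-0.05,0.05
HMDB0000389,2'-Deoxysepiapterin,0.07,0.09,0.63,0.57,0.21,0.45,-0.02,0.05,-0.01,0.05
HMDB0000511,Decanoic acid,0.06,0.09,0.31,0.54,0.73,0.48,-0.01,0.05,0.03,0.05
HMDB0035564,"6,8-Tricosanedione",0.06,0.08,-,-,-0.49,0.59,-,-,-0.02,0.05
HMDB0011628,Enoxolone,0.05,0.10,0.67,1.02,-,-,-,-,-,-
HMDB0040085,"2,5-Dipropyl-4-methylthiazole",0.05,0.10,0.38,0.52,0.03,0.53,0.12,0.05,0.02,0.05
HMDB0004624,"3b,7b-Dihydroxy-5-androsten-17-one",0.05,0.08,-0.24,0.57,-0.40,0.49,-0.03,0.05,0,0.05
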