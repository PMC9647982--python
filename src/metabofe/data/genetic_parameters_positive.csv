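hmdb_id,common_name,h2,se_h2,rg_fcr,se_rg_fcr,rg_rfi,se_rg_rfi,rp_fcr,se_rp_fcr,rp_rfi,se_rp_rfi
HMDB0001008,Biliverdin,0.70,0.13,0,0.21,-0.01,0.18,-0.03,0.06,-0.03,0.06
HMDB0029112,Tyrosyl-phenylalanine,0.57,0.13,0,0.22,-0.11,0.19,-0.02,0.05,-0.04,0.06
HMDB0003154,Canthaxanthin,0.38,0.12,-0.48,0.22,-0.45,0.20,-0.09,0.05,-0.13,0.05
HMDB0000501,7-Ketocholesterol,0.36,0.13,0.41,0.25,0.54,0.22,0.07,0.05,0.11,0.05
HMDB0004983,Dimethyl sulfone,0.33,0.12,0.40,0.26,0.30,0.23,-0.04,0.05,0,0.05
HMDB0038824,Hypoletin 8-gentiobioside,0.31,0.13,0.35,0.29,0.32,0.26,-0.05,0.05,-0.05,0.05
HMDB0000210,Pantothenic acid,0.29,0.11,0.16,0.26,0.20,0.23,0.16,0.05,0.15,0.05
HMDB0011567,Monoolein,0.29,0.12,-0.38,0.26,-0.27,0.24,-0.11,0.05,-0.05,0.05
HMDB0000251,Taurine,0.28,0.12,-0.15,0.28,0.04,0.25,0.04,0.05,0.03,0.05
HMDB0004992,Benzocaine,0.27,0.11,0.12,0.28,0.03,0.25,0.06,0.05,0,0.05
HMDB0000714,Hippuric acid,0.25,0.11,0.05,0.28,-0.10,0.25,0.04,0.05,-0.01,0.05
HMDB0003869,Epsilon-(gamma-glutamyl)-lysine,0.25,0.11,0.19,0.27,0.42,0.21,0.14,0.05,0.20,0.05
HMDB0000128,Guanidineacetic acid,0.24,0.11,-0.20,0.29,0.06,0.26,-0.04,0.05,0.01,0.05
HMDB0000357,beta Hydroxybutyrate,0.23,0.10,0.25,0.27,0.21,0.25,0.16,0.05,0.14,0.05
HMDB0011741,gamma-Glutamyltyrosine,0.22,0.10,-0.42,0.26,-0.39,0.25,-0.19,0.05,-0.18,0.05
HMDB0029081,Tryptophyl-glutamine,0.19,0.10,0.28,0.30,0.30,0.27,0.04,0.05,0.03,0.05
HMDB0006709,Coenzyme Q2,0.16,0.10,0.11,0.33,0.17,0.30,-0.02,0.05,-0.03,0.05
HMDB0000175,IMP,0.16,0.10,-0.24,0.33,-0.14,0.30,0,0.05,-0.01,0.05
HMDB0028691,L-Alanyl-L-leucine,0.15,0.11,-0.56,0.37,-0.03,0.31,0.06,0.05,0.06,0.05
HMDB0013651,"2-(14,15-Epoxyeicosatrienoyl) glycerol",0.15,0.09,0.25,0.33,0.26,0.31,-0.03,0.05,-0.02,0.05
HMDB0000378,2-Methylbutyroylcarnitine,0.14,0.11,0.72,0.33,0.74,0.35,0.20,0.05,0.16,0.05
HMDB0015655,Virilon,0.13,0.11,0.43,0.45,0.37,0.41,-0.08,0.05,-0.09,0.05
HMDB0011725,Sulfosalicylic acid,0.13,0.09,0.38,0.36,0.22,0.32,0.05,0.05,0.04,0.05
HMDB0011171,gamma-Glu-Leu,0.11,0.09,0.08,0.38,0.17,0.35,0.01,0.05,0.01,0.05
HMDB0013272,N-Lauroylglycine,0.11,0.09,-0.02,0.39,0.08,0.36,-0.01,0.05,-0.02,0.05
HMDB0000016,Desoxycortone,0.11,0.09,0.29,0.40,0.35,0.36,-0.02,0.05,-0.02,0.05
HMDB0001072,Ubiquinone-10,0.08,0.09,-0.47,0.45,-0.59,0.42,0.05,0.05,0.04,0.05
HMDB0062656,Linoleamide,0.08,0.09,0.37,0.46,0.44,0.42,-0.04,0.05,-0.04,0.05
HMDB0000201,Acetyl-L-carnitine,0.08,0.09,-0.01,0.42,0.13,0.38,0.18,0.05,0.13,0.05
HMDB0031048,Avocadyne 1-acetate,0.08,0.09,0.28,0.46,0.40,0.43,-0.03,0.05,-0.03,0.05
HMDB0002100,Palmitoyl ethanolamide,0.08,0.09,0.26,0.47,0.40,0.45,-0.04,0.05,-0.04,0.05
HMDB0001586,Glucose 1-phosphate,0.07,0.08,0.22,0.46,-0.10,0.41,-0.02,0.05,-0.03,0.05
HMDB0002117,Oleamide,0.07,0.08,0.28,0.48,0.34,0.46,-0.02,0.05,-0.01,0.05
HMDB0041857,Citrinin,0.06,0.08,0.51,0.56,0.67,0.53,-0.04,0.05,-0.05,0.05
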