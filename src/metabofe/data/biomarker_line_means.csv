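hmdb_id,common_name,ion_mode,mean_fat,mean_lean,rg_fcr,se_rg_fcr,rg_rfi,se_rg_rfi,h2,se_h2
HMDB0000501,7-Ketocholesterol,positive,2180.27,782.69,0.41,0.25,0.54,0.22,0.36,0.13
HMDB0004983,Dimethyl sulfone,positive,1935.83,770.09,0.40,0.26,0.30,0.23,0.33,0.12
HMDB0038824,Hypoletin 8-gentiobioside,positive,1783.14,625.76,0.35,0.29,0.32,0.26,0.31,0.13
HMDB0003869,Epsilon-(gamma-glutamyl)-lysine,positive,1531.94,851.93,0.19,0.27,0.42,0.21,0.25,0.11
HMDB0011741,gamma-Glutamyltyrosine,positive,720.39,1309.21,-0.42,0.26,-0.39,0.25,0.22,0.10
HMDB0000225,2-Oxoadipic acid,negative,1580.83,855.62,0.44,0.20,0.46,0.17,0.58,0.13
HMDB0000670,L-Homoarginine,negative,1762.28,670.93,0.34,0.23,0.37,0.20,0.53,0.13
HMDB0033338,Mollicellin F,negative,1418.72,806.64,0.38,0.23,0.25,0.21,0.43,0.13
HMDB0002833,Testosterone,negative,660.15,1114.50,-0.58,0.20,-0.58,0.18,0.43,0.12
HMDB0000045,Adenosine 5'-monophosphate,negative,1399.03,856.74,0.51,0.23,0.30,0.20,0.42,0.12
HMDB0002226,Adrenic acid,negative,766.70,1155.87,-0.68,0.23,-0.38,0.21,0.37,0.12
HMDB0062219,"(13Z,16Z)-Docosadienoic acid",negative,790.03,1248.22,-0.67,0.26,-0.42,0.23,0.33,0.12
HMDB0000308,3b-Hydroxy-5-cholenoic acid,negative,1045.31,257.59,0.39,0.31,0.66,0.28,0.24,0.12
HMDB0001903,Calcitriol,negative,869.84,5096.83,-0.38,0.32,-0.02,0.29,0.21,0.11
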