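trait,hybrid,treatment,mean
PH,P-1498,C,38.75
PH,P-1498,D,24.50
PH,P-1319,C,36.25
PH,P-1319,D,22.25
PH,DKC-6581,C,37.50
PH,DKC-6581,D,22.00
PH,DKC-6697,C,36.75
PH,DKC-6697,D,19.25
PH,N61X-3110,C,38.75
PH,N61X-3110,D,23.00
PH,N59B-311A,C,35.75
PH,N59B-311A,D,21.25
LA,P-1498,C,2600.07
LA,P-1498,D,600.93
LA,P-1319,C,2033.23
LA,P-1319,D,563.28
LA,DKC-6581,C,2353.26
LA,DKC-6581,D,582.54
LA,DKC-6697,C,2339.89
LA,DKC-6697,D,564.03
LA,N61X-3110,C,2128.37
LA,N61X-3110,D,569.95
LA,N59B-311A,C,1787.60
LA,N59B-311A,D,601.94
LN,P-1498,C,6.50
LN,P-1498,D,5.25
LN,P-1319,C,6.50
LN,P-1319,D,5.00
LN,DKC-6581,C,6.75
LN,DKC-6581,D,5.25
LN,DKC-6697,C,6.25
LN,DKC-6697,D,4.75
LN,N61X-3110,C,6.50
LN,N61X-3110,D,5.00
LN,N59B-311A,C,6.25
LN,N59B-311A,D,4.75
SPAD,P-1498,C,39.60
SPAD,P-1498,D,32.85
SPAD,P-1319,C,38.55
SPAD,P-1319,D,30.48
SPAD,DKC-6581,C,43.33
SPAD,DKC-6581,D,34.60
SPAD,DKC-6697,C,36.30
SPAD,DKC-6697,D,30.15
SPAD,N61X-3110,C,41.83
SPAD,N61X-3110,D,35.93
SPAD,N59B-311A,C,39.58
SPAD,N59B-311A,D,33.10
LRL,P-1498,C,59.25
LRL,P-1498,D,66.75
LRL,P-1319,C,56.00
LRL,P-1319,D,65.00
LRL,DKC-6581,C,58.25
LRL,DKC-6581,D,62.25
LRL,DKC-6697,C,55.75
LRL,DKC-6697,D,61.50
LRL,N61X-3110,C,57.50
LRL,N61X-3110,D,62.00
LRL,N59B-311A,C,55.75
LRL,N59B-311A,D,61.00
RN,P-1498,C,14.25
RN,P-1498,D,11.75
RN,P-1319,C,14.00
RN,P-1319,D,11.00
RN,DKC-6581,C,17.25
RN,DKC-6581,D,10.75
RN,DKC-6697,C,16.75
RN,DKC-6697,D,10.00
RN,N61X-3110,C,16.00
RN,N61X-3110,D,10.75
RN,N59B-311A,C,15.75
RN,N59B-311A,D,11.50
LDW,P-1498,C,7.63
LDW,P-1498,D,2.17
LDW,P-1319,C,6.66
LDW,P-1319,D,2.06
LDW,DKC-6581,C,7.91
LDW,DKC-6581,D,2.29
LDW,DKC-6697,C,7.22
LDW,DKC-6697,D,2.09
LDW,N61X-3110,C,6.42
LDW,N61X-3110,D,2.28
LDW,N59B-311A,C,5.20
LDW,N59B-311A,D,2.17
SDW,P-1498,C,3.75
SDW,P-1498,D,1.63
SDW,P-1319,C,3.57
SDW,P-1319,D,1.39
SDW,DKC-6581,C,5.00
SDW,DKC-6581,D,1.43
SDW,DKC-6697,C,4.62
SDW,DKC-6697,D,1.33
SDW,N61X-3110,C,4.18
SDW,N61X-3110,D,1.40
SDW,N59B-311A,C,3.20
SDW,N59B-311A,D,1.33
SHDW,P-1498,C,11.39
SHDW,P-1498,D,3.80
SHDW,P-1319,C,10.63
SHDW,P-1319,D,3.45
SHDW,DKC-6581,C,12.91
SHDW,DKC-6581,D,3.73
SHDW,DKC-6697,C,11.83
SHDW,DKC-6697,D,3.42
SHDW,N61X-3110,C,10.59
SHDW,N61X-3110,D,3.65
SHDW,N59B-311A,C,8.40
SHDW,N59B-311A,D,3.50
RDW,P-1498,C,1.15
RDW,P-1498,D,1.38
RDW,P-1319,C,1.09
RDW,P-1319,D,1.29
RDW,DKC-6581,C,1.29
RDW,DKC-6581,D,1.21
RDW,DKC-6697,C,1.22
RDW,DKC-6697,D,1.15
RDW,N61X-3110,C,1.22
RDW,N61X-3110,D,1.14
RDW,N59B-311A,C,0.94
RDW,N59B-311A,D,1.13
RSR,P-1498,C,0.10
RSR,P-1498,D,0.38
RSR,P-1319,C,0.10
RSR,P-1319,D,0.37
RSR,DKC-6581,C,0.11
RSR,DKC-6581,D,0.36
RSR,DKC-6697,C,0.11
RSR,DKC-6697,D,0.34
RSR,N61X-3110,C,0.11
RSR,N61X-3110,D,0.35
RSR,N59B-311A,C,0.11
RSR,N59B-311A,D,0.32
TDW,P-1498,C,12.10
TDW,P-1498,D,4.88
TDW,P-1319,C,11.71
TDW,P-1319,D,4.74
TDW,DKC-6581,C,14.20
TDW,DKC-6581,D,4.93
TDW,DKC-6697,C,13.24
TDW,DKC-6697,D,4.57
TDW,N61X-3110,C,11.81
TDW,N61X-3110,D,4.49
TDW,N59B-311A,C,9.33
TDW,N59B-311A,D,4.63
RSA,P-1498,C,705.54
RSA,P-1498,D,663.65
RSA,P-1319,C,945.96
RSA,P-1319,D,811.77
RSA,DKC-6581,C,1116.13
RSA,DKC-6581,D,742.54
RSA,DKC-6697,C,1105.68
RSA,DKC-6697,D,716.50
RSA,N61X-3110,C,983.60
RSA,N61X-3110,D,810.23
RSA,N59B-311A,C,916.94
RSA,N59B-311A,D,740.31
RD,P-1498,C,0.37
RD,P-1498,D,0.47
RD,P-1319,C,0.43
RD,P-1319,D,0.49
RD,DKC-6581,C,0.46
RD,DKC-6581,D,0.49
RD,DKC-6697,C,0.52
RD,DKC-6697,D,0.49
RD,N61X-3110,C,0.46
RD,N61X-3110,D,0.50
RD,N59B-311A,C,0.47
RD,N59B-311A,D,0.47
TRL,P-1498,C,6025.57
TRL,P-1498,D,4507.91
TRL,P-1319,C,7041.50
TRL,P-1319,D,5220.65
TRL,DKC-6581,C,7748.80
TRL,DKC-6581,D,4791.84
TRL,DKC-6697,C,6752.40
TRL,DKC-6697,D,4613.85
TRL,N61X-3110,C,6693.33
TRL,N61X-3110,D,5202.80
TRL,N59B-311A,C,6531.25
TRL,N59B-311A,D,5037.82
RV,P-1498,C,6.66
RV,P-1498,D,7.78
RV,P-1319,C,10.15
RV,P-1319,D,10.06
RV,DKC-6581,C,12.99
RV,DKC-6581,D,9.16
RV,DKC-6697,C,14.46
RV,DKC-6697,D,8.95
RV,N61X-3110,C,11.61
RV,N61X-3110,D,10.12
RV,N59B-311A,C,10.48
RV,N59B-311A,D,8.67
NRT,P-1498,C,38899.25
NRT,P-1498,D,21485.75
NRT,P-1319,C,40179.75
NRT,P-1319,D,23325.75
NRT,DKC-6581,C,42571.75
NRT,DKC-6581,D,28464.25
NRT,DKC-6697,C,32207.25
NRT,DKC-6697,D,23252.50
NRT,N61X-3110,C,33353.00
NRT,N61X-3110,D,23283.75
NRT,N59B-311A,C,41103.75
NRT,N59B-311A,D,25777.25
NRF,P-1498,C,49278.50
NRF,P-1498,D,37754.75
NRF,P-1319,C,64806.00
NRF,P-1319,D,47135.50
NRF,DKC-6581,C,79550.25
NRF,DKC-6581,D,42397.25
NRF,DKC-6697,C,73482.25
NRF,DKC-6697,D,38932.25
NRF,N61X-3110,C,69277.75
NRF,N61X-3110,D,48596.25
NRF,N59B-311A,C,65371.50
NRF,N59B-311A,D,47962.25
NRC,P-1498,C,4905.00
NRC,P-1498,D,2871.00
NRC,P-1319,C,5707.75
NRC,P-1319,D,3363.25
NRC,DKC-6581,C,6115.75
NRC,DKC-6581,D,2803.75
NRC,DKC-6697,C,5467.00
NRC,DKC-6697,D,2728.00
NRC,N61X-3110,C,5630.75
NRC,N61X-3110,D,3143.00
NRC,N59B-311A,C,5127.25
NRC,N59B-311A,D,3469.00
Phot,P-1498,C,35.83
Phot,P-1498,D,16.20
Phot,P-1319,C,30.48
Phot,P-1319,D,15.75
Phot,DKC-6581,C,42.13
Phot,DKC-6581,D,18.20
Phot,DKC-6697,C,36.98
Phot,DKC-6697,D,15.25
Phot,N61X-3110,C,42.78
Phot,N61X-3110,D,15.88
Phot,N59B-311A,C,40.90
Phot,N59B-311A,D,15.03
Fv/Fm,P-1498,C,0.49
Fv/Fm,P-1498,D,0.30
Fv/Fm,P-1319,C,0.45
Fv/Fm,P-1319,D,0.29
Fv/Fm,DKC-6581,C,0.42
Fv/Fm,DKC-6581,D,0.36
Fv/Fm,DKC-6697,C,0.42
Fv/Fm,DKC-6697,D,0.32
Fv/Fm,N61X-3110,C,0.48
Fv/Fm,N61X-3110,D,0.35
Fv/Fm,N59B-311A,C,0.47
Fv/Fm,N59B-311A,D,0.30
ETR,P-1498,C,197.27
ETR,P-1498,D,85.24
ETR,P-1319,C,191.75
ETR,P-1319,D,77.42
ETR,DKC-6581,C,236.78
ETR,DKC-6581,D,109.17
ETR,DKC-6697,C,225.14
ETR,DKC-6697,D,108.06
ETR,N61X-3110,C,210.93
ETR,N61X-3110,D,103.98
ETR,N59B-311A,C,208.56
ETR,N59B-311A,D,92.21
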