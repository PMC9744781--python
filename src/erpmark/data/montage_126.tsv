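# 126-channel 10/5 scalp montage (idealized spherical head, vertex-centered)
# label	theta_deg (angle from vertex)	phi_deg (azimuth: 0=nasion, +90=right ear)
Fpz	96.34	0.00
AFz	71.55	0.00
Fz	46.58	0.00
FCz	22.39	0.00
Cz	0.00	0.00
CPz	20.22	180.00
Pz	39.25	180.00
POz	58.43	180.00
Oz	77.50	180.00
Iz	95.79	180.00
Fp1	99.42	-19.57
Fp2	99.42	19.57
AF7	100.94	-39.17
AF8	100.94	39.17
AF3	80.48	-23.73
AF4	80.48	23.73
F7	100.64	-59.50
F8	100.64	59.50
F5	81.69	-52.79
F6	81.69	52.79
F3	64.59	-41.71
F4	64.59	41.71
F1	51.58	-24.52
F2	51.58	24.52
FT7	98.64	-80.45
FT8	98.64	80.45
FC5	74.46	-74.71
FC6	74.46	74.71
FC3	51.69	-65.29
FC4	51.69	65.29
FC1	32.01	-45.91
FC2	32.01	45.91
T7	95.28	-100.91
T8	95.28	100.91
C5	69.86	-97.35
C6	69.86	97.35
C3	45.75	-94.66
C4	45.75	94.66
C1	22.41	-92.56
C2	22.41	92.56
TP7	91.71	-118.49
TP8	91.71	118.49
CP5	69.13	-118.01
CP6	69.13	118.01
CP3	47.79	-122.00
CP4	47.79	122.00
CP1	29.41	-136.34
CP2	29.41	136.34
P7	87.69	-135.17
P8	87.69	135.17
P5	70.62	-137.29
P6	70.62	137.29
P3	55.28	-143.43
P4	55.28	143.43
P1	43.65	-157.55
P2	43.65	157.55
PO7	84.05	-150.31
PO8	84.05	150.31
PO3	66.18	-159.32
PO4	66.18	159.32
O1	80.61	-165.06
O2	80.61	165.06
FT9	121.36	-83.35
FT10	121.36	83.35
TP9	112.51	-120.58
TP10	112.51	120.58
P9	107.75	-136.54
P10	107.75	136.54
PO9	102.95	-151.43
PO10	102.95	151.43
AFp3h	88.09	-11.87
AFp4h	88.09	11.87
FFC1h	36.02	-18.01
FFC2h	36.02	18.01
CCP1h	15.16	-134.84
CCP2h	15.16	134.84
PPO9h	95.66	-143.97
PPO10h	95.66	143.97
AFF1h	59.99	-9.39
AFF2h	59.99	9.39
AFF5h	78.57	-37.86
AFF6h	78.57	37.86
FFC3h	48.61	-44.09
FFC4h	48.61	44.09
FFC5h	67.42	-58.72
FFC6h	67.42	58.72
FCC1h	15.67	-46.57
FCC2h	15.67	46.57
FCC3h	36.20	-74.59
FCC4h	36.20	74.59
FCC5h	59.65	-83.29
FCC6h	59.65	83.29
CCP3h	35.07	-111.44
CCP4h	35.07	111.44
CCP5h	57.53	-107.66
CCP6h	57.53	107.66
CPP1h	31.49	-162.82
CPP2h	31.49	162.82
CPP3h	42.83	-139.66
CPP4h	42.83	139.66
CPP5h	59.80	-129.92
CPP6h	59.80	129.92
PPO1h	49.53	-171.44
PPO2h	49.53	171.44
PPO5h	66.04	-147.73
PPO6h	66.04	147.73
POO1	68.65	-172.64
POO2	68.65	172.64
OI1h	88.15	-172.78
OI2h	88.15	172.78
FFT7h	88.81	-66.97
FFT8h	88.81	66.97
FTT7h	84.25	-88.52
FTT8h	84.25	88.52
TTP7h	81.27	-108.73
TTP8h	81.27	108.73
TPP7h	79.35	-127.34
TPP8h	79.35	127.34
POO9h	91.57	-158.36
POO10h	91.57	158.36
FFT9h	112.00	-72.34
FFT10h	112.00	72.34
TPP9h	100.25	-128.64
TPP10h	100.25	128.64
AFp1	85.60	-8.41
AFp2	85.60	8.41
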