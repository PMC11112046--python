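residue,hydrophobicity_kd,volume_a3,flexibility,fluctuation,polarity,isoelectric_point,helix_propensity,sheet_propensity,bulkiness,interface_propensity
A,1.8,88.6,0.357,0.984,8.1,6.00,1.42,0.83,11.50,0.89
R,-4.5,173.4,0.529,1.008,10.5,10.76,0.98,0.93,14.28,1.10
N,-3.5,114.1,0.463,1.048,11.6,5.41,0.67,0.89,12.82,0.97
D,-3.5,111.1,0.511,1.068,13.0,2.77,1.01,0.54,11.68,0.78
C,2.5,108.5,0.346,0.906,5.5,5.07,0.70,1.19,13.46,1.35
Q,-3.5,143.8,0.493,1.037,10.5,5.65,1.11,1.10,14.45,1.05
E,-3.5,138.4,0.497,1.094,12.3,3.22,1.51,0.37,13.57,0.73
G,-0.4,60.1,0.544,1.031,9.0,5.97,0.57,0.75,3.40,0.84
H,-3.2,153.2,0.323,0.950,10.4,7.59,1.00,0.87,13.69,1.09
I,4.5,166.7,0.462,0.927,5.2,6.02,1.08,1.60,21.40,1.24
L,3.8,166.7,0.365,0.935,4.9,5.98,1.21,1.30,21.40,1.18
K,-3.9,168.6,0.466,1.102,11.3,9.74,1.16,0.74,15.71,0.75
M,1.9,162.9,0.295,0.952,5.7,5.74,1.45,1.05,16.25,1.45
F,2.8,189.9,0.314,0.915,5.2,5.48,1.13,1.38,19.80,1.38
P,-1.6,112.7,0.509,1.049,8.0,6.30,0.57,0.55,17.43,0.93
S,-0.8,89.0,0.507,1.046,9.2,5.68,0.77,0.75,9.47,0.86
T,-0.7,116.1,0.444,0.997,8.6,5.60,0.83,1.19,15.77,0.86
W,-0.9,227.8,0.305,0.904,5.4,5.89,1.08,1.37,21.67,1.56
Y,-1.3,193.6,0.420,0.929,6.2,5.66,0.69,1.47,18.03,1.47
V,4.2,140.0,0.386,0.931,5.9,5.96,1.06,1.70,21.57,1.09
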