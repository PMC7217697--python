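residue,n_sites
A,4.00
C,1.62
D,1.89
E,3.95
F,0.32
G,2.06
H,2.88
I,1.00
K,0.54
L,0.60
M,1.12
N,1.89
P,2.59
Q,3.95
R,3.43
S,2.61
T,0.20
V,0.56
W,0.08
Y,0.42
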