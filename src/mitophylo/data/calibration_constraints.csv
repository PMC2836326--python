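node,lower_myr,upper_myr,basis
A,419,472,fossil
B,392,419,fossil
C,345,392,fossil
D,130,,fossil
E,284,,fossil
F,136,,fossil
G,112,,fossil
H,151,,fossil
I,94,,fossil
J,49,,fossil
K,146,,fossil
L,56,,fossil
M,49,,fossil
N,74,,fossil
O,94,,fossil
P,50,,fossil
Q,98,,fossil
R,32,,fossil
S,85,95,biogeographic
T,112,145,biogeographic
U,100,120,biogeographic
V,40,,fossil
W,40,,fossil
X,40,,fossil
Y,7.6,,fossil
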