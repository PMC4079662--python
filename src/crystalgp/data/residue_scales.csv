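aa,name3,gravy,sce,pol,category
A,ALA,1.8,0.00,8.1,S
R,ARG,-4.5,2.13,10.5,+
N,ASN,-3.5,0.97,11.6,P
D,ASP,-3.5,0.58,13.0,-
C,CYS,2.5,0.55,5.5,P
Q,GLN,-3.5,1.55,10.5,P
E,GLU,-3.5,1.17,12.3,-
G,GLY,-0.4,0.00,9.0,S
H,HIS,-3.2,0.84,10.4,+
I,ILE,4.5,0.89,5.2,H
L,LEU,3.8,0.78,4.9,H
K,LYS,-3.9,1.94,11.3,+
M,MET,1.9,1.61,5.7,H
F,PHE,2.8,0.58,5.2,H
P,PRO,-1.6,0.00,8.0,H
S,SER,-0.8,0.71,9.2,P
T,THR,-0.7,0.83,8.6,P
W,TRP,-0.9,0.97,5.4,H
Y,TYR,-1.3,0.99,6.2,H
V,VAL,4.2,0.51,5.9,H
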