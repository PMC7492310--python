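id,R1,R2,R3,pIC50,IC50_uM
a,-H,-Br,-H,5.1581,6.9490
b,-H,-NO2,-H,5.2999,5.0131
c,-F,-H,-H,5.3681,4.2843
d,-Cl,-H,-H,5.1022,7.9040
e,-F,-H,-F,5.4049,3.9362
f,-Cl,-H,-Cl,4.9666,10.7985
g,-Br,-Br,-H,5.1224,7.5440
h,-F,-F,-H,5.8668,1.3590
i,-Cl,-Cl,-H,4.9438,11.3808
j,-NO2,-H,-H,5.478,3.3265
k,-Br,-H,-Br,5.1535,7.0224
l,-NO2,-H,-NO2,5.7351,1.8403
template,-Br,-H,-H,5.257,5.5330
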