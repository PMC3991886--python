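name,length,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
DpsSSB,142,7.0,0.7,4.9,7.7,1.4,11.3,0.7,6.3,4.2,4.9,2.8,6.3,4.2,4.9,7.0,9.2,7.0,3.5,2.8,2.8
FpsSSB,140,4.3,1.4,5.0,9.3,4.3,6.4,2.1,7.9,10.0,5.0,2.1,7.1,2.1,2.1,2.9,8.0,10.7,6.4,1.4,3.6
ParSSB,213,8.0,0.0,5.6,4.2,3.3,16.4,1.4,5.2,4.2,3.3,1.9,8.0,4.7,12.2,4.7,5.6,4.2,2.8,0.9,3.3
PcrSSB,219,6.8,0.0,5.0,4.1,3.2,16.9,0.9,4.6,3.7,2.7,1.8,10.0,4.6,12.8,4.6,7.3,4.1,2.7,0.9,3.2
PinSSB,222,7.7,0.5,4.5,5.4,2.3,6.8,0.9,1.8,5.9,3.6,3.6,6.3,9.9,17.6,4.5,3.6,6.3,4.5,1.8,2.7
PprSSB,183,7.7,0.0,3.8,5.5,2.2,10.4,0.5,3.3,3.8,3.8,2.7,4.4,7.1,21.3,4.4,3.8,3.8,6.6,2.2,2.7
PtoSSB,151,5.3,2.0,5.3,9.9,3.3,6.0,2.0,5.3,10.6,4.6,2.6,4.6,7.3,5.3,2.6,3.3,9.3,6.0,1.3,3.3
EcoSSB,178,7.3,0.0,4.5,5.6,2.2,16.3,0.6,2.8,3.4,4.5,3.4,4.5,6.7,10.1,5.6,5.6,5.0,7.3,2.2,2.2
TteSSB3,150,4.0,0.0,10.7,8.0,6.0,6.0,0.7,5.3,5.3,7.3,2.0,4.0,6.0,1.3,6.0,6.7,8.0,8.7,2.0,1.3
TmaSSB,141,5.0,0.0,6.4,12.8,7.8,4.3,0.0,4.3,3.5,5.7,2.8,2.1,7.1,0.7,10.6,5.0,10.6,9.2,0.7,1.4
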