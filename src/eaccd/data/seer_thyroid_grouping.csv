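t,n,m,a,group,stage
T1,N0,M0,A1,1,I
T1,N0,M0,A2,1,I
T1,N1a,M0,A1,1,I
T1,N1a,M0,A2,1,II
T1,N1b,M0,A1,1,I
T2,N0,M0,A1,1,I
T2,N0,M0,A2,1,I
T2,N1a,M0,A1,1,I
T2,N1b,M0,A1,1,I
T3,N0,M0,A1,1,I
T3,N1a,M0,A1,1,I
T3,N1b,M0,A1,1,I
T4a,N0,M0,A1,1,I
T1,N1b,M0,A2,2,II
T2,N1a,M0,A2,2,II
T3,N0,M0,A2,2,II
T3,N1a,M0,A2,2,II
T4a,N1a,M0,A1,2,I
T4a,N1b,M0,A1,2,I
T4b,N1a,M0,A1,2,I
T2,N1b,M0,A2,3,II
T3,N1b,M0,A2,3,II
T3,N1b,M1,A1,3,II
T4b,N0,M0,A1,3,I
T4b,N1b,M0,A1,3,I
T4a,N0,M0,A2,4,III
T4a,N1a,M0,A2,4,III
T2,N0,M1,A2,5,IVB
T4a,N1b,M0,A2,5,III
T4a,N1b,M1,A1,5,II
T4b,N0,M0,A2,5,IVA
T4b,N1a,M0,A2,5,IVA
T1,N0,M1,A2,6,IVB
T3,N0,M1,A2,6,IVB
T3,N1b,M1,A2,6,IVB
T4a,N1b,M1,A2,6,IVB
T4b,N0,M1,A2,6,IVB
T4b,N1b,M0,A2,6,IVA
T4b,N1b,M1,A2,7,IVB
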