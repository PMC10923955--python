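t,n,m,stage_group
T1a,N0,M0,IA
T1a,N0,M1a,IV
T1a,N0,M1b,IV
T1a,N0,M1c,IV
T1a,N0,M1d,IV
T1a,N1a,M0,IIIA
T1a,N1a,M1a,IV
T1a,N1a,M1b,IV
T1a,N1a,M1c,IV
T1a,N1a,M1d,IV
T1a,N1b,M0,IIIB
T1a,N1b,M1a,IV
T1a,N1b,M1b,IV
T1a,N1b,M1c,IV
T1a,N1b,M1d,IV
T1a,N1c,M0,IIIB
T1a,N1c,M1a,IV
T1a,N1c,M1b,IV
T1a,N1c,M1c,IV
T1a,N1c,M1d,IV
T1a,N2a,M0,IIIA
T1a,N2a,M1a,IV
T1a,N2a,M1b,IV
T1a,N2a,M1c,IV
T1a,N2a,M1d,IV
T1a,N2b,M0,IIIB
T1a,N2b,M1a,IV
T1a,N2b,M1b,IV
T1a,N2b,M1c,IV
T1a,N2b,M1d,IV
T1a,N2c,M0,IIIC
T1a,N2c,M1a,IV
T1a,N2c,M1b,IV
T1a,N2c,M1c,IV
T1a,N2c,M1d,IV
T1a,N3a,M0,IIIC
T1a,N3a,M1a,IV
T1a,N3a,M1b,IV
T1a,N3a,M1c,IV
T1a,N3a,M1d,IV
T1a,N3b,M0,IIIC
T1a,N3b,M1a,IV
T1a,N3b,M1b,IV
T1a,N3b,M1c,IV
T1a,N3b,M1d,IV
T1a,N3c,M0,IIIC
T1a,N3c,M1a,IV
T1a,N3c,M1b,IV
T1a,N3c,M1c,IV
T1a,N3c,M1d,IV
T1b,N0,M0,IB
T1b,N0,M1a,IV
T1b,N0,M1b,IV
T1b,N0,M1c,IV
T1b,N0,M1d,IV
T1b,N1a,M0,IIIA
T1b,N1a,M1a,IV
T1b,N1a,M1b,IV
T1b,N1a,M1c,IV
T1b,N1a,M1d,IV
T1b,N1b,M0,IIIB
T1b,N1b,M1a,IV
T1b,N1b,M1b,IV
T1b,N1b,M1c,IV
T1b,N1b,M1d,IV
T1b,N1c,M0,IIIB
T1b,N1c,M1a,IV
T1b,N1c,M1b,IV
T1b,N1c,M1c,IV
T1b,N1c,M1d,IV
T1b,N2a,M0,IIIA
T1b,N2a,M1a,IV
T1b,N2a,M1b,IV
T1b,N2a,M1c,IV
T1b,N2a,M1d,IV
T1b,N2b,M0,IIIB
T1b,N2b,M1a,IV
T1b,N2b,M1b,IV
T1b,N2b,M1c,IV
T1b,N2b,M1d,IV
T1b,N2c,M0,IIIC
T1b,N2c,M1a,IV
T1b,N2c,M1b,IV
T1b,N2c,M1c,IV
T1b,N2c,M1d,IV
T1b,N3a,M0,IIIC
T1b,N3a,M1a,IV
T1b,N3a,M1b,IV
T1b,N3a,M1c,IV
T1b,N3a,M1d,IV
T1b,N3b,M0,IIIC
T1b,N3b,M1a,IV
T1b,N3b,M1b,IV
T1b,N3b,M1c,IV
T1b,N3b,M1d,IV
T1b,N3c,M0,IIIC
T1b,N3c,M1a,IV
T1b,N3c,M1b,IV
T1b,N3c,M1c,IV
T1b,N3c,M1d,IV
T2a,N0,M0,IB
T2a,N0,M1a,IV
T2a,N0,M1b,IV
T2a,N0,M1c,IV
T2a,N0,M1d,IV
T2a,N1a,M0,IIIA
T2a,N1a,M1a,IV
T2a,N1a,M1b,IV
T2a,N1a,M1c,IV
T2a,N1a,M1d,IV
T2a,N1b,M0,IIIB
T2a,N1b,M1a,IV
T2a,N1b,M1b,IV
T2a,N1b,M1c,IV
T2a,N1b,M1d,IV
T2a,N1c,M0,IIIB
T2a,N1c,M1a,IV
T2a,N1c,M1b,IV
T2a,N1c,M1c,IV
T2a,N1c,M1d,IV
T2a,N2a,M0,IIIA
T2a,N2a,M1a,IV
T2a,N2a,M1b,IV
T2a,N2a,M1c,IV
T2a,N2a,M1d,IV
T2a,N2b,M0,IIIB
T2a,N2b,M1a,IV
T2a,N2b,M1b,IV
T2a,N2b,M1c,IV
T2a,N2b,M1d,IV
T2a,N2c,M0,IIIC
T2a,N2c,M1a,IV
T2a,N2c,M1b,IV
T2a,N2c,M1c,IV
T2a,N2c,M1d,IV
T2a,N3a,M0,IIIC
T2a,N3a,M1a,IV
T2a,N3a,M1b,IV
T2a,N3a,M1c,IV
T2a,N3a,M1d,IV
T2a,N3b,M0,IIIC
T2a,N3b,M1a,IV
T2a,N3b,M1b,IV
T2a,N3b,M1c,IV
T2a,N3b,M1d,IV
T2a,N3c,M0,IIIC
T2a,N3c,M1a,IV
T2a,N3c,M1b,IV
T2a,N3c,M1c,IV
T2a,N3c,M1d,IV
T2b,N0,M0,IIA
T2b,N0,M1a,IV
T2b,N0,M1b,IV
T2b,N0,M1c,IV
T2b,N0,M1d,IV
T2b,N1a,M0,IIIB
T2b,N1a,M1a,IV
T2b,N1a,M1b,IV
T2b,N1a,M1c,IV
T2b,N1a,M1d,IV
T2b,N1b,M0,IIIB
T2b,N1b,M1a,IV
T2b,N1b,M1b,IV
T2b,N1b,M1c,IV
T2b,N1b,M1d,IV
T2b,N1c,M0,IIIB
T2b,N1c,M1a,IV
T2b,N1c,M1b,IV
T2b,N1c,M1c,IV
T2b,N1c,M1d,IV
T2b,N2a,M0,IIIB
T2b,N2a,M1a,IV
T2b,N2a,M1b,IV
T2b,N2a,M1c,IV
T2b,N2a,M1d,IV
T2b,N2b,M0,IIIB
T2b,N2b,M1a,IV
T2b,N2b,M1b,IV
T2b,N2b,M1c,IV
T2b,N2b,M1d,IV
T2b,N2c,M0,IIIC
T2b,N2c,M1a,IV
T2b,N2c,M1b,IV
T2b,N2c,M1c,IV
T2b,N2c,M1d,IV
T2b,N3a,M0,IIIC
T2b,N3a,M1a,IV
T2b,N3a,M1b,IV
T2b,N3a,M1c,IV
T2b,N3a,M1d,IV
T2b,N3b,M0,IIIC
T2b,N3b,M1a,IV
T2b,N3b,M1b,IV
T2b,N3b,M1c,IV
T2b,N3b,M1d,IV
T2b,N3c,M0,IIIC
T2b,N3c,M1a,IV
T2b,N3c,M1b,IV
T2b,N3c,M1c,IV
T2b,N3c,M1d,IV
T3a,N0,M0,IIA
T3a,N0,M1a,IV
T3a,N0,M1b,IV
T3a,N0,M1c,IV
T3a,N0,M1d,IV
T3a,N1a,M0,IIIB
T3a,N1a,M1a,IV
T3a,N1a,M1b,IV
T3a,N1a,M1c,IV
T3a,N1a,M1d,IV
T3a,N1b,M0,IIIB
T3a,N1b,M1a,IV
T3a,N1b,M1b,IV
T3a,N1b,M1c,IV
T3a,N1b,M1d,IV
T3a,N1c,M0,IIIB
T3a,N1c,M1a,IV
T3a,N1c,M1b,IV
T3a,N1c,M1c,IV
T3a,N1c,M1d,IV
T3a,N2a,M0,IIIB
T3a,N2a,M1a,IV
T3a,N2a,M1b,IV
T3a,N2a,M1c,IV
T3a,N2a,M1d,IV
T3a,N2b,M0,IIIB
T3a,N2b,M1a,IV
T3a,N2b,M1b,IV
T3a,N2b,M1c,IV
T3a,N2b,M1d,IV
T3a,N2c,M0,IIIC
T3a,N2c,M1a,IV
T3a,N2c,M1b,IV
T3a,N2c,M1c,IV
T3a,N2c,M1d,IV
T3a,N3a,M0,IIIC
T3a,N3a,M1a,IV
T3a,N3a,M1b,IV
T3a,N3a,M1c,IV
T3a,N3a,M1d,IV
T3a,N3b,M0,IIIC
T3a,N3b,M1a,IV
T3a,N3b,M1b,IV
T3a,N3b,M1c,IV
T3a,N3b,M1d,IV
T3a,N3c,M0,IIIC
T3a,N3c,M1a,IV
T3a,N3c,M1b,IV
T3a,N3c,M1c,IV
T3a,N3c,M1d,IV
T3b,N0,M0,IIB
T3b,N0,M1a,IV
T3b,N0,M1b,IV
T3b,N0,M1c,IV
T3b,N0,M1d,IV
T3b,N1a,M0,IIIC
T3b,N1a,M1a,IV
T3b,N1a,M1b,IV
T3b,N1a,M1c,IV
T3b,N1a,M1d,IV
T3b,N1b,M0,IIIC
T3b,N1b,M1a,IV
T3b,N1b,M1b,IV
T3b,N1b,M1c,IV
T3b,N1b,M1d,IV
T3b,N1c,M0,IIIC
T3b,N1c,M1a,IV
T3b,N1c,M1b,IV
T3b,N1c,M1c,IV
T3b,N1c,M1d,IV
T3b,N2a,M0,IIIC
T3b,N2a,M1a,IV
T3b,N2a,M1b,IV
T3b,N2a,M1c,IV
T3b,N2a,M1d,IV
T3b,N2b,M0,IIIC
T3b,N2b,M1a,IV
T3b,N2b,M1b,IV
T3b,N2b,M1c,IV
T3b,N2b,M1d,IV
T3b,N2c,M0,IIIC
T3b,N2c,M1a,IV
T3b,N2c,M1b,IV
T3b,N2c,M1c,IV
T3b,N2c,M1d,IV
T3b,N3a,M0,IIIC
T3b,N3a,M1a,IV
T3b,N3a,M1b,IV
T3b,N3a,M1c,IV
T3b,N3a,M1d,IV
T3b,N3b,M0,IIIC
T3b,N3b,M1a,IV
T3b,N3b,M1b,IV
T3b,N3b,M1c,IV
T3b,N3b,M1d,IV
T3b,N3c,M0,IIIC
T3b,N3c,M1a,IV
T3b,N3c,M1b,IV
T3b,N3c,M1c,IV
T3b,N3c,M1d,IV
T4a,N0,M0,IIB
T4a,N0,M1a,IV
T4a,N0,M1b,IV
T4a,N0,M1c,IV
T4a,N0,M1d,IV
T4a,N1a,M0,IIIC
T4a,N1a,M1a,IV
T4a,N1a,M1b,IV
T4a,N1a,M1c,IV
T4a,N1a,M1d,IV
T4a,N1b,M0,IIIC
T4a,N1b,M1a,IV
T4a,N1b,M1b,IV
T4a,N1b,M1c,IV
T4a,N1b,M1d,IV
T4a,N1c,M0,IIIC
T4a,N1c,M1a,IV
T4a,N1c,M1b,IV
T4a,N1c,M1c,IV
T4a,N1c,M1d,IV
T4a,N2a,M0,IIIC
T4a,N2a,M1a,IV
T4a,N2a,M1b,IV
T4a,N2a,M1c,IV
T4a,N2a,M1d,IV
T4a,N2b,M0,IIIC
T4a,N2b,M1a,IV
T4a,N2b,M1b,IV
T4a,N2b,M1c,IV
T4a,N2b,M1d,IV
T4a,N2c,M0,IIIC
T4a,N2c,M1a,IV
T4a,N2c,M1b,IV
T4a,N2c,M1c,IV
T4a,N2c,M1d,IV
T4a,N3a,M0,IIIC
T4a,N3a,M1a,IV
T4a,N3a,M1b,IV
T4a,N3a,M1c,IV
T4a,N3a,M1d,IV
T4a,N3b,M0,IIIC
T4a,N3b,M1a,IV
T4a,N3b,M1b,IV
T4a,N3b,M1c,IV
T4a,N3b,M1d,IV
T4a,N3c,M0,IIIC
T4a,N3c,M1a,IV
T4a,N3c,M1b,IV
T4a,N3c,M1c,IV
T4a,N3c,M1d,IV
T4b,N0,M0,IIC
T4b,N0,M1a,IV
T4b,N0,M1b,IV
T4b,N0,M1c,IV
T4b,N0,M1d,IV
T4b,N1a,M0,IIIC
T4b,N1a,M1a,IV
T4b,N1a,M1b,IV
T4b,N1a,M1c,IV
T4b,N1a,M1d,IV
T4b,N1b,M0,IIIC
T4b,N1b,M1a,IV
T4b,N1b,M1b,IV
T4b,N1b,M1c,IV
T4b,N1b,M1d,IV
T4b,N1c,M0,IIIC
T4b,N1c,M1a,IV
T4b,N1c,M1b,IV
T4b,N1c,M1c,IV
T4b,N1c,M1d,IV
T4b,N2a,M0,IIIC
T4b,N2a,M1a,IV
T4b,N2a,M1b,IV
T4b,N2a,M1c,IV
T4b,N2a,M1d,IV
T4b,N2b,M0,IIIC
T4b,N2b,M1a,IV
T4b,N2b,M1b,IV
T4b,N2b,M1c,IV
T4b,N2b,M1d,IV
T4b,N2c,M0,IIIC
T4b,N2c,M1a,IV
T4b,N2c,M1b,IV
T4b,N2c,M1c,IV
T4b,N2c,M1d,IV
T4b,N3a,M0,IIID
T4b,N3a,M1a,IV
T4b,N3a,M1b,IV
T4b,N3a,M1c,IV
T4b,N3a,M1d,IV
T4b,N3b,M0,IIID
T4b,N3b,M1a,IV
T4b,N3b,M1b,IV
T4b,N3b,M1c,IV
T4b,N3b,M1d,IV
T4b,N3c,M0,IIID
T4b,N3c,M1a,IV
T4b,N3c,M1b,IV
T4b,N3c,M1c,IV
T4b,N3c,M1d,IV
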