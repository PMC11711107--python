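sample,SiO2,Al2O3,Fe2O3,MgO,CaO,Na2O,K2O,TiO2,MnO,P2O5,Other,LOI110,LOI1000
ATD,74.3,8.9,2.6,1.2,2.9,1.6,2.3,0.4,0.1,0.1,0.08,0.6,3.8
GDD,63.4,9.0,3.5,1.6,9.1,1.8,2.0,0.6,0.1,0.1,0.07,0.3,8.9
SVA,53.9,19.1,8.0,3.6,8.7,3.5,0.6,0.9,0.2,0.1,0.01,0.4,0.2
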