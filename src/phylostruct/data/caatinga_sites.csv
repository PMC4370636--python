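site,municipality,substrate,lat,lon,NRI_all,NRI_wood,NRI_herb,NTI_all,NTI_wood,NTI_herb
s01,"Crateús, CE",crystalline,-5.133,-40.866,2.52,5.63,-1.07,1.97,2.30,1.63
s02,"Floresta, PE",crystalline,-8.312,-38.195,-0.01,1.55,-1.17,1.88,3.51,1.15
s03,"Quixadá, CE",crystalline,-4.826,-38.969,2.93,4.92,-0.03,2.78,3.03,2.96
s04,"Floresta, PE",crystalline,-8.309,-38.202,1.39,2.98,-0.55,1.76,3.00,1.15
s05,"Floresta, PE",crystalline,-8.476,-38.480,1.20,2.78,-0.58,2.07,2.94,1.67
s06,"Crateús, CE",sedimentary,-5.167,-40.933,3.46,5.31,-0.66,2.39,3.44,-0.01
s07,"Crateús, CE",sedimentary,-5.133,-40.900,5.70,9.19,-1.91,1.73,2.65,1.12
s08,"São José do Piauí, PI",sedimentary,-6.854,-41.471,3.42,4.94,-2.07,1.77,3.51,-1.19
s09,"Quixadá, CE",inselberg,-4.956,-39.024,-0.59,1.07,-0.73,-0.17,0.00,1.33
s10,"São Joaquim do Monte, PE",inselberg,-8.382,-35.844,-4.19,-0.05,-3.58,-1.87,1.34,-2.52
s11,"Agrestina, PE",inselberg,-8.391,-36.010,-2.69,0.92,-2.96,-0.75,1.62,-1.10
s12,"Esperança, PB",inselberg,-7.017,-35.881,-3.34,0.95,-2.57,-0.98,1.75,-0.04
s13,"Feira de Santana, BA",inselberg,-12.272,-39.061,-2.23,-1.85,-0.12,-1.91,-2.08,0.72
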