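series,coefficient,rate,offset,c,p,grade
government,99982.37,0.0967,-91550.39,0.1580,1,Excellent
social,101479.15,0.1221,-91448.45,0.1234,1,Excellent
out_of_pocket,113692.50,0.0886,-104036.18,0.0927,1,Excellent
gdp,7233636.83,0.0794,-6695057.83,0.0824,1,Excellent
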