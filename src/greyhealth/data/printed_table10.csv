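year,pharmaceutical,the,share
2023,23528.40,92069.52,25.56
2024,24696.45,101328.73,24.37
2025,25922.50,111519.12,23.24
2026,27209.40,122734.33,22.17
2027,28560.20,135077.43,21.14
2028,29978.06,148661.85,20.17
2029,31466.30,163612.41,19.23
2030,33028.43,180066.53,18.34
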