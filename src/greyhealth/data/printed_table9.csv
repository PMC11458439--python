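year,the,government,government_share,social,social_share,out_of_pocket,out_of_pocket_share,gdp,the_share_of_gdp
2023,96939.02,26680.58,27.52,44689.89,46.10,25568.56,26.38,1323708.42,7.32
2024,107820.96,29388.53,27.26,50494.01,46.83,27938.43,25.91,1433157.49,7.52
2025,119951.20,32371.32,26.99,57051.93,47.56,30527.95,25.45,1551656.22,7.73
2026,133475.92,35656.86,26.71,64461.58,48.29,33357.48,24.99,1679952.85,7.95
2027,148558.69,39275.86,26.44,72833.55,49.03,36449.28,24.54,1818857.53,8.17
2028,165382.65,43262.17,26.16,82292.84,49.76,39827.65,24.08,1969247.35,8.40
2029,184152.87,47653.07,25.88,92980.65,50.49,43519.14,23.63,2132071.95,8.64
2030,205098.97,52489.63,25.59,105056.55,51.22,47552.79,23.19,2308359.49,8.89
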