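year,total,outpatient,outpatient_share,hospital,hospital_share,retail,retail_share,pharma_share_of_the
2012,11860.45,4082.74,34.42,4171.31,35.17,3606.40,30.41,40.37
2013,13307.70,4102.65,30.83,5043.48,37.90,4161.57,31.27,39.80
2014,13925.00,4203.43,30.19,5086.89,36.53,4634.67,33.28,37.20
2015,16166.34,5065.84,31.34,5674.11,35.10,5426.39,33.57,37.16
2016,17602.44,5471.30,31.08,6053.59,34.39,6077.55,34.53,36.32
2017,18203.00,5959.95,32.74,6037.84,33.17,6205.21,34.09,34.42
2018,19148.98,6286.22,32.83,6074.27,31.72,6788.50,35.45,32.37
2019,21116.82,7227.06,34.22,6490.30,30.74,7399.46,35.04,33.31
2020,20699.90,7093.89,34.27,5769.35,27.87,7836.66,37.86,30.98
2021,20395.63,7848.64,38.48,6242.58,30.61,6304.41,30.91,28.67
2022,21275.81,8303.04,39.03,5848.79,27.49,7123.98,33.48,26.91
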