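period,government_vsv,government_crsv,social_vsv,social_crsv,out_of_pocket_vsv,out_of_pocket_crsv,dsv
2012-2013,0.15,5.00,0.31,10.33,2.54,84.67,3.00
2013-2014,-0.18,4.35,2.07,50.00,-1.89,45.65,4.14
2014-2015,0.49,8.99,2.24,41.10,-2.72,49.91,5.45
2015-2016,-0.44,23.78,0.92,49.73,-0.49,26.49,1.85
2016-2017,-1.10,49.55,1.11,50.00,-0.01,0.45,2.22
2017-2018,-1.17,43.82,1.34,50.19,-0.16,5.99,2.67
2018-2019,-0.38,30.65,0.61,49.19,-0.25,20.16,1.24
2019-2020,3.04,50.00,-2.33,38.32,-0.71,11.68,6.08
2020-2021,-3.49,49.15,3.56,50.14,-0.05,0.70,7.10
2021-2022,1.26,49.80,-0.56,22.13,-0.71,28.06,2.53
2012-2022,-1.82,11.71,9.27,59.65,-4.45,28.64,15.54
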