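period,outpatient_vsv,outpatient_crsv,hospital_vsv,hospital_crsv,retail_vsv,retail_crsv,dsv
2012-2013,-3.59,50.00,2.73,38.02,0.86,11.98,7.18
2013-2014,-0.64,15.92,-1.37,34.08,2.01,50.00,4.02
2014-2015,1.15,40.07,-1.43,49.83,0.29,10.10,2.87
2015-2016,-0.26,13.47,-0.71,36.79,0.96,49.74,1.93
2016-2017,1.66,50.00,-1.22,36.75,-0.44,13.25,3.32
2017-2018,0.09,3.10,-1.45,50.00,1.36,46.90,2.90
2018-2019,1.39,50.00,-0.98,35.25,-0.41,14.75,2.78
2019-2020,0.05,0.87,-2.87,50.00,2.82,49.13,5.74
2020-2021,4.21,30.29,2.74,19.71,-6.95,50.00,13.90
2021-2022,0.55,8.81,-3.12,50.00,2.57,41.19,6.24
2012-2022,4.61,30.01,-7.68,50.00,3.07,19.99,15.36
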