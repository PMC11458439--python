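period,hospitals_vsv,hospitals_crsv,outpatient_clinics_vsv,outpatient_clinics_crsv,pharmaceutical_retail_vsv,pharmaceutical_retail_crsv,public_health_vsv,public_health_crsv,health_admin_insurance_vsv,health_admin_insurance_crsv,others_vsv,others_crsv,dsv
2012-2013,0.18,13.33,-0.57,42.22,0.17,12.59,-0.11,8.15,0.02,1.48,0.30,22.22,1.35
2013-2014,-0.81,22.13,-0.59,16.12,-0.07,1.91,-0.36,9.84,1.34,36.61,0.49,13.39,3.66
2014-2015,0.21,12.43,-0.10,5.92,0.09,5.33,-0.46,27.22,-0.29,17.16,0.54,31.95,1.69
2015-2016,0.17,10.63,-0.29,18.13,0.07,4.37,-0.51,31.88,0.14,8.75,0.42,26.25,1.60
2016-2017,0.69,26.74,0.19,7.36,-0.81,31.40,-0.20,7.75,-0.28,10.85,0.41,15.89,2.58
2017-2018,0.32,35.56,0.12,13.33,-0.13,14.44,-0.27,30.00,0.01,1.11,-0.05,5.56,0.90
2018-2019,0.64,32.32,0.15,7.58,0.07,3.54,-0.11,5.56,0.13,6.57,-0.88,44.44,1.98
2019-2020,-3.42,46.85,-0.22,3.01,0.06,0.82,1.09,14.93,2.01,27.53,0.50,6.85,7.30
2020-2021,-2.02,11.58,-1.31,7.51,-0.55,3.15,-0.93,5.33,3.08,17.66,-9.55,54.76,7.76
2021-2022,-2.26,49.02,0.07,1.52,0.15,3.25,-0.04,0.87,1.45,31.45,0.64,13.88,4.61
2012-2022,-0.74,6.02,-1.01,8.22,-3.27,26.61,-1.13,9.19,3.67,29.86,2.47,20.10,12.29
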