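year,hospitals,outpatient_clinics,pharmaceutical_retail,public_health,health_admin_insurance,others
2012,62.15,8.00,12.28,7.49,2.27,7.82
2013,62.33,7.43,12.45,7.38,2.29,8.12
2014,61.52,6.84,12.38,7.02,3.63,8.61
2015,61.73,6.74,12.47,6.56,3.34,9.15
2016,61.90,6.45,12.54,6.05,3.48,9.57
2017,62.59,6.64,11.73,5.85,3.20,9.98
2018,62.91,6.76,11.60,5.58,3.21,9.93
2019,63.55,6.91,11.67,5.47,3.34,9.05
2020,60.13,6.69,11.73,6.56,5.35,9.55
2021,63.67,6.92,8.86,6.40,4.49,9.65
2022,61.41,6.99,9.01,6.36,5.94,10.29
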