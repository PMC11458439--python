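component,growth_rate,crsv,driving_force
government,11.05,11.73,129.57
social,14.35,59.83,858.60
out_of_pocket,9.04,28.44,257.06
hospitals,12.00,6.02,72.27
outpatient_clinics,7.78,8.22,63.91
pharmaceutical_retail,12.36,26.61,328.88
public_health,9.43,9.19,86.72
health_admin_insurance,17.04,29.86,508.76
others,15.06,20.10,302.73
outpatient_pharma,7.36,30.01,220.79
hospital_pharma,3.44,50.00,171.89
retail_pharma,7.04,19.99,140.80
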