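year,total,government,government_share,social,social_share,out_of_pocket,out_of_pocket_share,the_share_of_gdp
2012,28119.00,8431.98,29.99,10030.70,35.67,9656.32,31.34,5.22
2013,31668.95,9545.81,30.14,11393.79,35.98,10729.34,33.88,5.34
2014,35312.40,10579.23,29.96,13437.75,38.05,11295.41,31.99,5.49
2015,40974.64,12475.28,30.45,16506.71,40.29,11992.65,29.27,5.95
2016,46344.88,13910.31,30.01,19096.68,41.21,13337.90,28.78,6.21
2017,52598.28,15205.87,28.91,22258.81,42.32,15133.60,28.77,6.32
2018,59121.91,16399.13,27.74,25810.78,43.66,16911.99,28.61,6.43
2019,65841.39,18016.95,27.36,29150.57,44.27,18673.87,28.36,6.67
2020,72175.00,21941.90,30.40,30273.67,41.94,19959.43,27.65,7.10
2021,76844.99,20676.06,26.91,34963.26,45.50,21205.67,27.60,6.72
2022,85327.49,24040.89,28.17,38345.67,44.94,22940.94,26.89,7.05
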