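code,name,p_weight,food_production,raw_material_production,water_supply,gas_regulation,climate_regulation,environment_purification,hydrological_regulation,soil_conservation,nutrient_cycling,biodiversity,aesthetic_landscape
1,cropland,3,0.85,0.40,0.02,0.67,0.36,0.10,0.27,1.03,0.12,0.13,0.06
2,forestland,2,0.27,0.63,0.33,2.07,6.20,1.80,3.86,2.52,0.19,2.30,1.01
3,other_forestland,2,0.19,0.43,0.22,1.41,4.23,1.28,3.35,1.72,0.13,1.57,0.69
4,high_coverage_grassland,2,0.23,0.34,0.19,1.21,3.19,1.05,2.34,1.47,0.11,1.34,0.59
5,medium_coverage_grassland,2,0.00,0.29,0.16,1.03,2.71,0.89,1.99,1.25,0.00,1.14,0.50
6,low_coverage_grassland,2,0.00,0.20,0.00,0.73,1.91,0.63,1.40,0.00,0.00,0.80,0.35
7,water,2,0.80,0.23,8.29,0.77,2.29,5.55,102.24,0.93,0.07,2.55,1.89
8,wetland,2,0.51,0.50,2.59,1.90,3.60,3.60,24.23,2.31,0.18,7.87,4.73
9,urban,4,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
10,unutilized,1,0.01,0.02,0.01,0.07,0.05,0.21,0.12,0.08,0.01,0.07,0.03
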