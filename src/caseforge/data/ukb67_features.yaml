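# Default 67-trait feature set: 30 blood biochemistry, 20 blood count,
# 4 urine assay, 3 spirometry, 4 body size, 3 blood pressure measures and
# the sex / age / fasting-time covariates. Population means and SDs are
# round mid-adult reference values used only by the synthetic generator.
- {name: alanine_aminotransferase, unit: U/L, panel: blood_biochemistry, mean: 23.5, sd: 14.0, missing_rate: 0.035}
- {name: albumin, unit: g/L, panel: blood_biochemistry, mean: 45.2, sd: 2.6, missing_rate: 0.09}
- {name: alkaline_phosphatase, unit: U/L, panel: blood_biochemistry, mean: 83.6, sd: 26.0, missing_rate: 0.035}
- {name: apolipoprotein_a, unit: g/L, panel: blood_biochemistry, mean: 1.54, sd: 0.27, missing_rate: 0.09}
- {name: apolipoprotein_b, unit: g/L, panel: blood_biochemistry, mean: 1.03, sd: 0.24, missing_rate: 0.04}
- {name: aspartate_aminotransferase, unit: U/L, panel: blood_biochemistry, mean: 26.2, sd: 10.6, missing_rate: 0.04}
- {name: c_reactive_protein, unit: mg/L, panel: blood_biochemistry, mean: 2.6, sd: 4.4, missing_rate: 0.035}
- {name: calcium, unit: mmol/L, panel: blood_biochemistry, mean: 2.38, sd: 0.09, missing_rate: 0.09}
- {name: cholesterol, unit: mmol/L, panel: blood_biochemistry, mean: 5.69, sd: 1.14, missing_rate: 0.035}
- {name: creatinine, unit: umol/L, panel: blood_biochemistry, mean: 72.4, sd: 17.7, missing_rate: 0.035}
- {name: cystatin_c, unit: mg/L, panel: blood_biochemistry, mean: 0.91, sd: 0.17, missing_rate: 0.035}
- {name: direct_bilirubin, unit: umol/L, panel: blood_biochemistry, mean: 1.78, sd: 0.66, missing_rate: 0.12}
- {name: gamma_glutamyltransferase, unit: U/L, panel: blood_biochemistry, mean: 37.4, sd: 41.0, missing_rate: 0.035}
- {name: glucose, unit: mmol/L, panel: blood_biochemistry, mean: 5.12, sd: 1.21, missing_rate: 0.09}
- {name: glycated_haemoglobin, unit: mmol/mol, panel: blood_biochemistry, mean: 36.1, sd: 6.7, missing_rate: 0.04}
- {name: hdl_cholesterol, unit: mmol/L, panel: blood_biochemistry, mean: 1.45, sd: 0.38, missing_rate: 0.09}
- {name: igf_1, unit: nmol/L, panel: blood_biochemistry, mean: 21.4, sd: 5.7, missing_rate: 0.04}
- {name: ldl_direct, unit: mmol/L, panel: blood_biochemistry, mean: 3.56, sd: 0.87, missing_rate: 0.035}
- {name: lipoprotein_a, unit: nmol/L, panel: blood_biochemistry, mean: 44.1, sd: 49.6, missing_rate: 0.20}
- {name: oestradiol, unit: pmol/L, panel: blood_biochemistry, mean: 110.1, sd: 112.0, missing_rate: 0.85,
   special_imputation: {kind: sex_constant, male: 36.71, female: 110.13}}
- {name: phosphate, unit: mmol/L, panel: blood_biochemistry, mean: 1.16, sd: 0.16, missing_rate: 0.09}
- {name: rheumatoid_factor, unit: IU/ml, panel: blood_biochemistry, mean: 0.0, sd: 12.0, missing_rate: 0.85,
   special_imputation: {kind: constant, value: 0.0}}
- {name: shbg, unit: nmol/L, panel: blood_biochemistry, mean: 51.8, sd: 27.6, missing_rate: 0.09}
- {name: testosterone, unit: nmol/L, panel: blood_biochemistry, mean: 6.6, sd: 6.0, missing_rate: 0.09,
   special_imputation: {kind: sex_median}}
- {name: total_bilirubin, unit: umol/L, panel: blood_biochemistry, mean: 9.1, sd: 4.4, missing_rate: 0.035}
- {name: total_protein, unit: g/L, panel: blood_biochemistry, mean: 72.5, sd: 4.0, missing_rate: 0.09}
- {name: triglycerides, unit: mmol/L, panel: blood_biochemistry, mean: 1.75, sd: 1.02, missing_rate: 0.035}
- {name: urate, unit: umol/L, panel: blood_biochemistry, mean: 309.0, sd: 80.3, missing_rate: 0.035}
- {name: urea, unit: mmol/L, panel: blood_biochemistry, mean: 5.42, sd: 1.39, missing_rate: 0.035}
- {name: vitamin_d, unit: nmol/L, panel: blood_biochemistry, mean: 49.8, sd: 21.1, missing_rate: 0.06}
- {name: white_blood_cell_count, unit: 10^9/L, panel: blood_count, mean: 6.89, sd: 2.0, missing_rate: 0.025}
- {name: red_blood_cell_count, unit: 10^12/L, panel: blood_count, mean: 4.51, sd: 0.41, missing_rate: 0.025}
- {name: haemoglobin_concentration, unit: g/dL, panel: blood_count, mean: 14.2, sd: 1.23, missing_rate: 0.025}
- {name: haematocrit_percentage, unit: '%', panel: blood_count, mean: 41.1, sd: 3.5, missing_rate: 0.025}
- {name: mean_corpuscular_volume, unit: fL, panel: blood_count, mean: 91.1, sd: 4.4, missing_rate: 0.025}
- {name: mean_corpuscular_haemoglobin, unit: pg, panel: blood_count, mean: 31.5, sd: 1.8, missing_rate: 0.025}
- {name: mean_corpuscular_haemoglobin_concentration, unit: g/dL, panel: blood_count, mean: 34.6, sd: 1.0, missing_rate: 0.025}
- {name: red_cell_distribution_width, unit: '%', panel: blood_count, mean: 13.5, sd: 0.95, missing_rate: 0.025}
- {name: platelet_count, unit: 10^9/L, panel: blood_count, mean: 252.0, sd: 59.5, missing_rate: 0.025}
- {name: platelet_crit, unit: '%', panel: blood_count, mean: 0.235, sd: 0.05, missing_rate: 0.025}
- {name: mean_platelet_volume, unit: fL, panel: blood_count, mean: 9.35, sd: 1.1, missing_rate: 0.025}
- {name: platelet_distribution_width, unit: '%', panel: blood_count, mean: 16.5, sd: 0.46, missing_rate: 0.025}
- {name: lymphocyte_count, unit: 10^9/L, panel: blood_count, mean: 1.95, sd: 0.74, missing_rate: 0.03}
- {name: monocyte_count, unit: 10^9/L, panel: blood_count, mean: 0.48, sd: 0.2, missing_rate: 0.03}
- {name: neutrophil_count, unit: 10^9/L, panel: blood_count, mean: 4.2, sd: 1.4, missing_rate: 0.03}
- {name: eosinophil_count, unit: 10^9/L, panel: blood_count, mean: 0.17, sd: 0.13, missing_rate: 0.03}
- {name: basophil_count, unit: 10^9/L, panel: blood_count, mean: 0.03, sd: 0.04, missing_rate: 0.03}
- {name: nucleated_red_blood_cell_count, unit: 10^9/L, panel: blood_count, mean: 0.002, sd: 0.01, missing_rate: 0.03}
- {name: reticulocyte_count, unit: 10^12/L, panel: blood_count, mean: 0.06, sd: 0.02, missing_rate: 0.04}
- {name: immature_reticulocyte_fraction, unit: ratio, panel: blood_count, mean: 0.29, sd: 0.06, missing_rate: 0.04}
- {name: microalbumin_in_urine, unit: mg/L, panel: urine_assay, mean: 25.7, sd: 77.0, missing_rate: 0.69}
- {name: creatinine_in_urine, unit: umol/L, panel: urine_assay, mean: 8941.0, sd: 5677.0, missing_rate: 0.035}
- {name: potassium_in_urine, unit: mmol/L, panel: urine_assay, mean: 63.6, sd: 33.8, missing_rate: 0.035}
- {name: sodium_in_urine, unit: mmol/L, panel: urine_assay, mean: 77.4, sd: 43.5, missing_rate: 0.035}
- {name: fev1, unit: L, panel: spirometry, mean: 2.84, sd: 0.78, missing_rate: 0.16}
- {name: fvc, unit: L, panel: spirometry, mean: 3.74, sd: 0.99, missing_rate: 0.16}
- {name: peak_expiratory_flow, unit: L/min, panel: spirometry, mean: 389.0, sd: 121.0, missing_rate: 0.16}
- {name: body_mass_index, unit: kg/m^2, panel: body_size, mean: 27.4, sd: 4.8, missing_rate: 0.006}
- {name: weight, unit: kg, panel: body_size, mean: 78.1, sd: 15.9, missing_rate: 0.006}
- {name: waist_circumference, unit: cm, panel: body_size, mean: 90.3, sd: 13.5, missing_rate: 0.005}
- {name: standing_height, unit: cm, panel: body_size, mean: 168.5, sd: 9.3, missing_rate: 0.005}
- {name: systolic_blood_pressure, unit: mmHg, panel: blood_pressure, mean: 138.0, sd: 18.6, missing_rate: 0.05}
- {name: diastolic_blood_pressure, unit: mmHg, panel: blood_pressure, mean: 82.2, sd: 10.1, missing_rate: 0.05}
- {name: pulse_rate, unit: bpm, panel: blood_pressure, mean: 69.4, sd: 11.3, missing_rate: 0.05}
- {name: sex, unit: '', panel: covariates, role: categorical}
- {name: age, unit: years, panel: covariates, mean: 57.0, sd: 8.0, role: covariate}
- {name: fasting_time, unit: hours, panel: covariates, mean: 3.8, sd: 2.4, missing_rate: 0.01, role: covariate}
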