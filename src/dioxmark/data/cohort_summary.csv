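congener_id,matrix,median,q1,q3,n_detect,n_total
2378-TeCDD,maternal_blood,0.76,0.66,0.96,34,41
2378-TeCDD,cord_blood,1.0,0.96,1.0,4,41
2378-TeCDD,cord_tissue,0.83,0.73,1.1,14,41
12378-PeCDD,maternal_blood,3.7,2.7,4.3,41,41
12378-PeCDD,cord_blood,2.0,1.6,2.5,36,41
12378-PeCDD,cord_tissue,3.8,2.9,5.0,40,41
123478-HxCDD,maternal_blood,0.16,0.12,0.2,39,41
123478-HxCDD,cord_blood,0.15,0.14,0.17,4,41
123478-HxCDD,cord_tissue,0.15,0.12,0.16,15,41
123678-HxCDD,maternal_blood,1.5,1.1,1.8,41,41
123678-HxCDD,cord_blood,0.68,0.56,0.8,41,41
123678-HxCDD,cord_tissue,0.94,0.67,1.1,41,41
123789-HxCDD,maternal_blood,0.23,0.18,0.3,41,41
123789-HxCDD,cord_blood,0.18,0.14,0.21,32,41
123789-HxCDD,cord_tissue,0.23,0.17,0.3,24,41
1234678-HpCDD,maternal_blood,0.11,0.087,0.16,41,41
1234678-HpCDD,cord_blood,0.046,0.035,0.068,41,41
1234678-HpCDD,cord_tissue,0.063,0.052,0.085,41,41
OCDD,maternal_blood,0.016,0.012,0.023,41,41
OCDD,cord_blood,0.0041,0.0027,0.0058,41,41
OCDD,cord_tissue,0.005,0.0043,0.0075,41,41
2378-TeCDF,maternal_blood,0.078,0.066,0.094,40,41
2378-TeCDF,cord_blood,0.073,0.064,0.089,24,41
2378-TeCDF,cord_tissue,0.078,0.051,0.11,15,41
12378-PeCDF,maternal_blood,0.020,0.017,0.024,21,41
12378-PeCDF,cord_blood,0.028,0.027,0.032,5,41
12378-PeCDF,cord_tissue,0.02,0.018,0.027,6,41
23478-PeCDF,maternal_blood,3.1,2.6,4.2,41,41
23478-PeCDF,cord_blood,1.5,1.2,2.0,41,41
23478-PeCDF,cord_tissue,3.1,2.5,3.9,41,41
123478-HxCDF,maternal_blood,0.25,0.21,0.33,41,41
123478-HxCDF,cord_blood,0.14,0.11,0.18,39,41
123478-HxCDF,cord_tissue,0.27,0.22,0.31,40,41
123678-HxCDF,maternal_blood,0.33,0.29,0.45,41,41
123678-HxCDF,cord_blood,0.23,0.18,0.3,41,41
123678-HxCDF,cord_tissue,0.31,0.24,0.36,41,41
123789-HxCDF,maternal_blood,1e-4,8e-5,1.3e-4,0,41
123789-HxCDF,cord_blood,1e-4,8e-5,1.3e-4,0,41
123789-HxCDF,cord_tissue,1e-4,8e-5,1.3e-4,0,41
234678-HxCDF,maternal_blood,0.14,0.098,0.18,39,41
234678-HxCDF,cord_blood,0.11,0.1,0.12,16,41
234678-HxCDF,cord_tissue,0.12,0.089,0.16,29,41
1234678-HpCDF,maternal_blood,0.023,0.019,0.034,41,41
1234678-HpCDF,cord_blood,0.017,0.014,0.024,39,41
1234678-HpCDF,cord_tissue,0.024,0.018,0.028,39,41
1234789-HpCDF,maternal_blood,1e-4,8e-5,1.3e-4,0,41
1234789-HpCDF,cord_blood,1e-4,8e-5,1.3e-4,0,41
1234789-HpCDF,cord_tissue,1e-4,8e-5,1.3e-4,0,41
OCDF,maternal_blood,1.4e-4,1.3e-4,1.4e-4,3,41
OCDF,cord_blood,1.3e-4,1.2e-4,1.4e-4,0,41
OCDF,cord_tissue,1.3e-4,1.2e-4,1.4e-4,0,41
PCB77,maternal_blood,5.3e-4,4.2e-4,6.6e-4,41,41
PCB77,cord_blood,3.8e-4,3.1e-4,5.2e-4,40,41
PCB77,cord_tissue,3.8e-4,3.1e-4,5.3e-4,40,41
PCB81,maternal_blood,1.1e-4,8.5e-5,1.6e-4,41,41
PCB81,cord_blood,9.2e-5,7.6e-5,1.1e-4,18,41
PCB81,cord_tissue,1.3e-4,9.4e-5,1.7e-4,33,41
PCB105,maternal_blood,0.1,0.071,0.15,41,41
PCB105,cord_blood,0.049,0.031,0.068,41,41
PCB105,cord_tissue,0.075,0.06,0.11,41,41
PCB114,maternal_blood,0.12,0.095,0.2,41,41
PCB114,cord_blood,0.058,0.040,0.090,41,41
PCB114,cord_tissue,0.092,0.079,0.13,41,41
PCB118,maternal_blood,0.48,0.31,0.64,41,41
PCB118,cord_blood,0.21,0.14,0.33,41,41
PCB118,cord_tissue,0.35,0.24,0.44,41,41
PCB123,maternal_blood,6.9e-3,5.2e-3,9.3e-3,41,41
PCB123,cord_blood,3.4e-3,2.7e-3,5.8e-3,41,41
PCB123,cord_tissue,5.4e-3,3.8e-3,7.2e-3,41,41
PCB126,maternal_blood,2.5,1.8,3.3,41,41
PCB126,cord_blood,1.0,0.76,1.5,41,41
PCB126,cord_tissue,1.7,1.3,2.3,41,41
PCB156,maternal_blood,0.81,0.58,1.2,41,41
PCB156,cord_blood,0.27,0.2,0.44,41,41
PCB156,cord_tissue,0.46,0.39,0.62,41,41
PCB157,maternal_blood,0.2,0.15,0.3,41,41
PCB157,cord_blood,0.08,0.059,0.13,41,41
PCB157,cord_tissue,0.12,0.10,0.17,41,41
PCB167,maternal_blood,6e-3,4.5e-3,8.2e-3,41,41
PCB167,cord_blood,2.3e-3,1.8e-3,3.5e-3,41,41
PCB167,cord_tissue,3.6e-3,2.6e-3,4.7e-3,41,41
PCB169,maternal_blood,0.22,0.18,0.29,41,41
PCB169,cord_blood,0.076,0.058,0.10,41,41
PCB169,cord_tissue,0.12,0.098,0.15,41,41
PCB189,maternal_blood,1.8e-2,1.4e-2,2.4e-2,41,41
PCB189,cord_blood,5.1e-3,4.0e-3,7.6e-3,41,41
PCB189,cord_tissue,8.1e-3,6.6e-3,1.0e-2,41,41
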