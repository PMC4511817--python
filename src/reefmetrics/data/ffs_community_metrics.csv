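class_label,mean_surface_complexity,se_surface_complexity,percent_cover,mean_percent_slope,se_percent_slope,mean_curv_combined,se_curv_combined,mean_curv_profile,se_curv_profile,mean_curv_planform,se_curv_planform
A. cytherea,4.59,0.68,0.32,3614,536,0.32,0.09,-0.41,0.06,-0.09,0.05
M. capitata,1.71,0.06,0.19,323.3,42,0.07,0.02,-0.09,0.01,-0.02,0.01
M. patula,1.81,0.13,0.11,546,159,0.16,0.05,-0.16,0.03,0.00,0.02
P. compressa,3.02,0.29,1.07,1299,182,0.12,0.05,-0.20,0.03,-0.08,0.02
P. lobata,2.12,0.04,10.96,733.7,30.6,0.17,0.01,-0.19,0.01,-0.02,0.00
P. meandrina,2.30,0.41,0.03,1438,744,0.42,0.28,-0.49,0.17,-0.08,0.14
rock/rubble,1.35,0.05,74.75,568,131,-0.02,0.02,-0.03,0.01,-0.05,0.01
sand,1.29,0.05,12.56,275.5,68,-0.02,0.01,-0.05,0.01,-0.06,0.01
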