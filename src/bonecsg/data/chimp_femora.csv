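specimen_id,sex,age_years,side,femur_length_mm,voxel_size_mm,stage,age_source
MPITC_11787,M,0.04,L,63.1,0.015,1,documented
MPITC_15015,,0.18,R,71.3,0.014,1,documented
MPITC_15003,,0.64,R,88.6,0.016,2,length_estimated
MPITC_14993,F,0.74,R,102.5,0.058,2,documented
MPITC_15000,,1.23,R,105.6,0.058,2,year_only
MPITC_13432,M,1.77,R,121.5,0.015,2,documented
MPITC_11777,M,2.13,R,125.4,0.015,2,documented
MPITC_11788,F,3.76,R,164.2,0.055,3,documented
MPITC_14995,M,5.24,L,174.7,0.091,4,documented
MPITC_14992,,5.84,R,186.7,0.091,4,length_estimated
MPITC_11791,F,6.45,L,192.1,0.091,4,documented
MPITC_15011,M,6.63,R,173.3,0.091,4,year_only
MPITC_13433,M,7.61,L,228.0,0.091,4,documented
MPITC_11782,M,8.34,L,209.8,0.091,4,year_only
MPITC_15020,F,9.98,L,223.5,0.091,4,documented
MPITC_13437,F,11.4,R,240.9,0.091,5,documented
MPITC_11776,F,12.38,R,245.4,0.091,5,year_only
MPITC_11779,M,12.57,L,268.5,0.091,5,year_only
NHM_Z.D.1846.10.23.11,,3.99,R,163.1,0.044,3,length_estimated
NHM_Z.D.1976.436,F,11.26,R,239.7,0.065,5,length_estimated
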