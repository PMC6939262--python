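nest_id,social_male,social_female,status,offspring_id,genetic_sire,lay_date
N1,M1,F1,primary_polygynous,O1,M1,10
N1,M1,F1,primary_polygynous,O2,M2,10
N2,M2,I1,monogamous,O3,M2,20
N3,M1,D,secondary_polygynous,O4,A,30
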