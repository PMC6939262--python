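nest_id,nestling_age,lay_date,time_of_day,male_rate,female_rate,status
N1,3,10,morning,5.0,6.0,primary_polygynous
N1,8,10,afternoon,4.0,7.0,primary_polygynous
N2,2,20,morning,6.0,5.5,monogamous
N2,10,20,afternoon,5.0,6.5,monogamous
N3,4,30,morning,1.0,9.0,secondary_polygynous
N3,9,30,afternoon,2.0,8.0,secondary_polygynous
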