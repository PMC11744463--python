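# Illustrative NHS-style unit costs, GBP, 2019-2020 price year.
# Synthetic fixture: magnitudes are realistic but these are NOT published reference costs.
item,unit_cost_gbp,unit
surgery_episode,2050.0,per episode
theatre_minute,12.0,per minute
bed_day,350.0,per day
ae_attendance,180.0,per attendance
readmission,1500.0,per episode
primary_care_visit,39.0,per visit
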