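item,category,unit,cost_gbp,source_label
setup_per_participant,intervention,per participant,68.0,calibration default (reference set-up aggregate)
sachet,intervention,per sachet,1.5,calibration default (formula-diet tariff)
practitioner_minute,intervention,per minute,0.7526,calibration default (practitioner staff cost)
visit_default_minutes,intervention,minutes per visit,25.0,calibration default (average appointment duration)
contact_GP,primary care,per contact,42.0,"staff-cost schedule, synthetic default"
contact_nurse,primary care,per contact,11.0,"staff-cost schedule, synthetic default"
contact_healthcare_assistant,primary care,per contact,7.0,"staff-cost schedule, synthetic default"
contact_other,other,per contact,75.0,"staff-cost schedule, synthetic default"
contact_secondary_care,secondary care,per contact,253.0,"national schedule, synthetic default"
hospital_elective,hospital,per episode,3800.0,"national schedule, synthetic default"
hospital_non_elective,hospital,per episode,2800.0,"national schedule, synthetic default"
excess_bed_day,hospital,per day,343.0,"national tariff, synthetic default"
trim_point_elective,hospital,days,9.0,"national tariff, synthetic default"
trim_point_non_elective,hospital,days,7.0,"national tariff, synthetic default"
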