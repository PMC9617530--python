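# Shipped strategy fixtures: the three primary arms with the full
# audit-derived pathway table and calibrated roster defaults.
standard_care:
  name: standard_care
  arrivals:
    annual_volume: 10542.0
    demand_multiplier: 1.0
    mode: calendar
    interarrival_mean_minutes: 16.2778
    window_minutes_per_week: 3300.010915384615
  prevalence: 0.0476
  pathway:
    noncancer:
      mammogram: 0.012766
      mammogram_ultrasound: 0.272533
      mammogram_ultrasound_biopsy: 0.035168
      ultrasound: 0.394921
      ultrasound_mammogram: 0.181688
      ultrasound_mammogram_biopsy: 0.023445
      ultrasound_biopsy: 0.060947
      biopsy: 0.017845
      mammogram_biopsy: 0.000686
    cancer:
      mammogram: 0.005525
      mammogram_ultrasound: 0.038122
      mammogram_ultrasound_biopsy: 0.510497
      ultrasound: 0.013812
      ultrasound_mammogram: 0.025414
      ultrasound_mammogram_biopsy: 0.340331
      ultrasound_biopsy: 0.035912
      biopsy: 0.027624
      mammogram_biopsy: 0.002762
    mammogram_first_probability: 0.6
    discharge_after_assessment_probability_noncancer: 0.25
  durations:
    central:
      initial_assessment: 10.0
      mammogram: 20.0
      ultrasound: 20.0
    biopsy_options:
    - 30.0
    - 45.0
    biopsy_mix: 0.5
    relative_half_width: 0.25
    prep_minutes: 5.0
  triage:
    arm: standard_care
    sensitivity: 0.98
    specificity: 0.2
    gp_override_probability: 0.0
    delayed_return_probability_cancer: 1.0
    delayed_return_probability_noncancer: 0.0
    delay_weeks: 6.0
    turnaround_minutes: 0.0
  booking:
    base_new_slots_full: 25
    base_new_slots_addon: 10
    queue_threshold: 380
    queue_step: 15
    first_boost_at: 385
    max_new_slots: 34
    overspill_slots_full: 5
    overspill_slots_addon: 6
    notice_days: 7.0
  roster:
    full_session:
      consultant: 2
      nurse_practitioner: 1
      physician_associate: 1
      band7_sonographer: 2
      band6_sonographer: 1
      band6_non_sonographer: 1
      grade2_assistant: 2
    addon_session:
      consultant: 1
      nurse_practitioner: 1
      physician_associate: 1
      band7_sonographer: 1
      band6_sonographer: 1
      band6_non_sonographer: 1
      grade2_assistant: 1
    availability:
      consultant: 0.805
      nurse_practitioner: 0.805
      physician_associate: 0.805
      band7_sonographer: 0.805
      band6_sonographer: 0.805
      band6_non_sonographer: 0.805
      grade2_assistant: 0.805
    availability_mode: stochastic_round
    rooms:
      initial_assessment: 4
      mammogram: 3
      ultrasound: 4
      biopsy: 4
  disabled_sessions: []
  warmup_weeks: 12
  collection_weeks: 52
  overtime_minutes: 15.0
scenario1:
  name: scenario1
  arrivals:
    annual_volume: 10542.0
    demand_multiplier: 1.0
    mode: calendar
    interarrival_mean_minutes: 16.2778
    window_minutes_per_week: 3300.010915384615
  prevalence: 0.0476
  pathway:
    noncancer:
      mammogram: 0.012766
      mammogram_ultrasound: 0.272533
      mammogram_ultrasound_biopsy: 0.035168
      ultrasound: 0.394921
      ultrasound_mammogram: 0.181688
      ultrasound_mammogram_biopsy: 0.023445
      ultrasound_biopsy: 0.060947
      biopsy: 0.017845
      mammogram_biopsy: 0.000686
    cancer:
      mammogram: 0.005525
      mammogram_ultrasound: 0.038122
      mammogram_ultrasound_biopsy: 0.510497
      ultrasound: 0.013812
      ultrasound_mammogram: 0.025414
      ultrasound_mammogram_biopsy: 0.340331
      ultrasound_biopsy: 0.035912
      biopsy: 0.027624
      mammogram_biopsy: 0.002762
    mammogram_first_probability: 0.6
    discharge_after_assessment_probability_noncancer: 0.25
  durations:
    central:
      initial_assessment: 10.0
      mammogram: 20.0
      ultrasound: 20.0
    biopsy_options:
    - 30.0
    - 45.0
    biopsy_mix: 0.5
    relative_half_width: 0.25
    prep_minutes: 5.0
  triage:
    arm: pinpoint
    sensitivity: 0.98
    specificity: 0.2
    gp_override_probability: 0.0
    delayed_return_probability_cancer: 1.0
    delayed_return_probability_noncancer: 0.0
    delay_weeks: 6.0
    turnaround_minutes: 0.0
  booking:
    base_new_slots_full: 25
    base_new_slots_addon: 10
    queue_threshold: 380
    queue_step: 15
    first_boost_at: 385
    max_new_slots: 34
    overspill_slots_full: 5
    overspill_slots_addon: 6
    notice_days: 7.0
  roster:
    full_session:
      consultant: 2
      nurse_practitioner: 1
      physician_associate: 1
      band7_sonographer: 2
      band6_sonographer: 1
      band6_non_sonographer: 1
      grade2_assistant: 2
    addon_session:
      consultant: 1
      nurse_practitioner: 1
      physician_associate: 1
      band7_sonographer: 1
      band6_sonographer: 1
      band6_non_sonographer: 1
      grade2_assistant: 1
    availability:
      consultant: 0.805
      nurse_practitioner: 0.805
      physician_associate: 0.805
      band7_sonographer: 0.805
      band6_sonographer: 0.805
      band6_non_sonographer: 0.805
      grade2_assistant: 0.805
    availability_mode: stochastic_round
    rooms:
      initial_assessment: 4
      mammogram: 3
      ultrasound: 4
      biopsy: 4
  disabled_sessions: []
  warmup_weeks: 12
  collection_weeks: 52
  overtime_minutes: 15.0
scenario2:
  name: scenario2
  arrivals:
    annual_volume: 10542.0
    demand_multiplier: 1.0
    mode: calendar
    interarrival_mean_minutes: 16.2778
    window_minutes_per_week: 3300.010915384615
  prevalence: 0.0476
  pathway:
    noncancer:
      mammogram: 0.012766
      mammogram_ultrasound: 0.272533
      mammogram_ultrasound_biopsy: 0.035168
      ultrasound: 0.394921
      ultrasound_mammogram: 0.181688
      ultrasound_mammogram_biopsy: 0.023445
      ultrasound_biopsy: 0.060947
      biopsy: 0.017845
      mammogram_biopsy: 0.000686
    cancer:
      mammogram: 0.005525
      mammogram_ultrasound: 0.038122
      mammogram_ultrasound_biopsy: 0.510497
      ultrasound: 0.013812
      ultrasound_mammogram: 0.025414
      ultrasound_mammogram_biopsy: 0.340331
      ultrasound_biopsy: 0.035912
      biopsy: 0.027624
      mammogram_biopsy: 0.002762
    mammogram_first_probability: 0.6
    discharge_after_assessment_probability_noncancer: 0.25
  durations:
    central:
      initial_assessment: 10.0
      mammogram: 20.0
      ultrasound: 20.0
    biopsy_options:
    - 30.0
    - 45.0
    biopsy_mix: 0.5
    relative_half_width: 0.25
    prep_minutes: 5.0
  triage:
    arm: pinpoint
    sensitivity: 0.98
    specificity: 0.2
    gp_override_probability: 0.2
    delayed_return_probability_cancer: 1.0
    delayed_return_probability_noncancer: 0.1
    delay_weeks: 6.0
    turnaround_minutes: 0.0
  booking:
    base_new_slots_full: 25
    base_new_slots_addon: 10
    queue_threshold: 380
    queue_step: 15
    first_boost_at: 385
    max_new_slots: 34
    overspill_slots_full: 5
    overspill_slots_addon: 6
    notice_days: 7.0
  roster:
    full_session:
      consultant: 2
      nurse_practitioner: 1
      physician_associate: 1
      band7_sonographer: 2
      band6_sonographer: 1
      band6_non_sonographer: 1
      grade2_assistant: 2
    addon_session:
      consultant: 1
      nurse_practitioner: 1
      physician_associate: 1
      band7_sonographer: 1
      band6_sonographer: 1
      band6_non_sonographer: 1
      grade2_assistant: 1
    availability:
      consultant: 0.805
      nurse_practitioner: 0.805
      physician_associate: 0.805
      band7_sonographer: 0.805
      band6_sonographer: 0.805
      band6_non_sonographer: 0.805
      grade2_assistant: 0.805
    availability_mode: stochastic_round
    rooms:
      initial_assessment: 4
      mammogram: 3
      ultrasound: 4
      biopsy: 4
  disabled_sessions: []
  warmup_weeks: 12
  collection_weeks: 52
  overtime_minutes: 15.0
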