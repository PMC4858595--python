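# Plausibility limits per volume category over the 120-day recall window.
# A reported volume strictly above its limit is an "unrealistic answer" and
# excludes the whole case.  The hospital-days limit equals the recall window
# itself; the remaining limits are deliberately high but within credibility
# and are user-editable.
recall_days: 120
limits:
  gp_contacts: 60
  emergency_visits: 30
  hospital_days: 120
  ambulance_rides: 30
  mental_health_contacts: 60
  school_absence_hours: 500
  attendance_officer_contacts: 30
  work_absence_hours: 500
  household_hours_missed: 500
  other_activity_hours_missed: 500
  youth_family_center_contacts: 60
  family_care_contacts: 120
  police_contacts: 60
  youth_police_contacts: 60
  court_proceedings: 20
  child_protection_contacts: 60
  child_health_protection_contacts: 60
  cigarette_packs: 360
  soft_drug_units: 500
  hard_drug_units: 500
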