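# SYNTHETIC example unit-cost table (Euro) in the style of the Dutch costing
# manuals.  Prices and index factors are illustrative placeholders, NOT the
# published manual values; supply your own table for a real evaluation.
reference_year: 2014
index_factors:
  2012: 0.975
  2013: 0.988
  2014: 1.0
categories:
  gp_contacts:                      {unit_price: 33.00,  price_year: 2013, sector: health_care}
  emergency_visits:                 {unit_price: 259.00, price_year: 2013, sector: health_care}
  hospital_days:                    {unit_price: 476.00, price_year: 2013, sector: health_care}
  ambulance_rides:                  {unit_price: 523.00, price_year: 2013, sector: health_care}
  mental_health_contacts:           {unit_price: 98.00,  price_year: 2013, sector: health_care}
  school_absence_hours:             {unit_price: 5.50,   price_year: 2014, sector: education}
  attendance_officer_contacts:      {unit_price: 27.00,  price_year: 2014, sector: education}
  work_absence_hours:               {unit_price: 13.50,  price_year: 2014, sector: labor_social_security}
  household_hours_missed:           {unit_price: 13.00,  price_year: 2014, sector: household_leisure}
  other_activity_hours_missed:      {unit_price: 12.50,  price_year: 2014, sector: household_leisure}
  youth_family_center_contacts:     {unit_price: 73.00,  price_year: 2014, sector: household_leisure}
  family_care_contacts:             {unit_price: 38.00,  price_year: 2014, sector: household_leisure}
  police_contacts:                  {unit_price: 333.00, price_year: 2012, sector: criminal_justice}
  youth_police_contacts:            {unit_price: 178.00, price_year: 2012, sector: criminal_justice}
  court_proceedings:                {unit_price: 1000.00, price_year: 2012, sector: criminal_justice}
  child_protection_contacts:        {unit_price: 120.00, price_year: 2012, sector: criminal_justice}
  child_health_protection_contacts: {unit_price: 95.00,  price_year: 2012, sector: criminal_justice}
  cigarette_packs:                  {unit_price: 6.00,   price_year: 2014, sector: substance_use}
  soft_drug_units:                  {unit_price: 9.00,   price_year: 2014, sector: substance_use}
  hard_drug_units:                  {unit_price: 25.00,  price_year: 2014, sector: substance_use}
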