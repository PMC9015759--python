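# Default de-identification scheme set.
#
# Edges for household income, insurance probability, PM2.5, ozone, and roadway
# proximity are the published defaults for the asthma use case; age uses the
# HIPAA-compliant 5-bin scheme with 89 as the oldest permissible age.
# Closure: first interval closed on both ends, later intervals (a, b];
# roadway distance uses left-closed integer-meter bins [a, a+50).

identifiers:
  - patient_id
  - birth_date
  - x_m
  - y_m
  - geocode
  - blockgroup_id
  - date
  # raw (secondary-PHI) exposure estimates; only their bins may appear
  - avg_daily_pm25
  - avg_max_daily_ozone
  - roadway_distance
  - prob_no_insurance
  - median_income

schemes:
  - feature: AgeStudyStart
    strategy: age
    source: birth_date

  - feature: Sex
    strategy: categorical_passthrough
    source: sex
    categories: [female, male]

  - feature: Race
    strategy: categorical_passthrough
    source: race
    categories: [Caucasian, African American, Asian, American/Alaskan Native,
                 Native Hawaiian/Pacific Islander, Unknown/other]

  - feature: Ethnicity
    strategy: categorical_passthrough
    source: ethnicity
    categories: [Hispanic, Not Hispanic, Unknown]

  - feature: EstResidentialDensity
    strategy: categorical_passthrough
    source: density_class
    categories: [rural, urban cluster, urbanized]

  - feature: EstProbabilityNoHealthIns
    strategy: explicit_edges
    source: prob_no_insurance
    edges: [0.0, 0.0637, 0.1121, 0.1644, 0.5548]

  - feature: EstHouseholdIncome
    strategy: explicit_edges
    source: median_income
    edges: [7470, 36635, 46750, 59566, 78355, 250001]

  - feature: MajorRoadwayHighwayExposure
    strategy: explicit_edges
    source: roadway_distance
    closure: left
    edges: [0, 50, 100, 150, 200, 250, .inf]
    labels: ["0-49", "50-99", "100-149", "150-199", "200-249", ">=250"]

  - feature: AvgDailyPM25Exposure
    strategy: explicit_edges
    source: avg_daily_pm25
    edges: [3.27, 6.30, 7.81, 10.83]

  - feature: MaxDailyOzoneExposure
    strategy: explicit_edges
    source: avg_max_daily_ozone
    edges: [27.80, 39.00, 42.73, 46.45]

  - feature: TotalEDInpatientVisits
    strategy: count_passthrough
    source: TotalEDInpatientVisits

  - feature: TotalPrednisoneRx
    strategy: count_passthrough
    source: TotalPrednisoneRx
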