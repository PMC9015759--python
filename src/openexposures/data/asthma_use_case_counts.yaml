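# Published summary counts from the asthma use case of an open
# clinical/environmental association service (cohort N=157,410, study year
# 2016). These are aggregate, de-identified counts: cohort marginals per
# feature bin, and per-bin outcome counts for the reported associations.
#
# They serve two purposes in this package:
#   * default marginal/effect specifications for the synthetic generator,
#     so simulated cohorts emulate the published cohort structure;
#   * inputs for recomputing the published chi-square statistics from their
#     contingency counts (see scripts/acceptance.py).

n_total: 157410
study_year: 2016

outcomes:
  ed:
    feature: TotalEDInpatientVisits
    description: "1 or more annual ED or inpatient visits for respiratory issues"
    n_positive: 26332
    prevalence: 0.1673
  prednisone:
    feature: TotalPrednisoneRx
    description: "1 or more annual prednisone prescriptions"
    n_positive: 17056
    prevalence: 0.1084

# Cohort marginals (counts over N=157,410, missing shown explicitly).
marginals:
  AgeStudyStart:
    "<5": 5638
    "5-17": 20071
    "18-44": 35777
    "45-64": 51495
    "65-89": 44429
  Sex:
    male: 67875
    female: 89531
    missing: 4
  Race:
    Caucasian: 78418
    African American: 28977
    Asian: 1608
    American/Alaskan Native: 902
    Native Hawaiian/Pacific Islander: 67
    Unknown/other: 47438
  Ethnicity:
    Hispanic: 7488
    Not Hispanic: 105925
    Unknown: 43997
  EstResidentialDensity:
    rural: 95632
    urban cluster: 41798
    urbanized: 0
    missing: 19980
  EstProbabilityNoHealthIns:
    "[0, 0.0637]": 34500
    "(0.0637, 0.1121]": 34313
    "(0.1121, 0.1644]": 34340
    "(0.1644, 0.5548]": 34201
    missing: 20056
  EstHouseholdIncome:
    "[7470, 36635]": 26967
    "(36635, 46750]": 27081
    "(46750, 59566]": 26843
    "(59566, 78355]": 26968
    "(78355, 250001]": 26955
    missing: 22596
  MajorRoadwayHighwayExposure:
    "0-49": 17485
    "50-99": 9754
    "100-149": 10244
    "150-199": 9398
    "200-249": 8477
    ">=250": 85989
    missing: 46694
  AvgDailyPM25Exposure:
    "[3.27, 6.3]": 8806
    "(6.3, 7.81]": 108847
    "(7.81, 10.83]": 23359
    missing: 16398
  MaxDailyOzoneExposure:
    "[27.8, 39]": 11608
    "(39, 42.73]": 127202
    "(42.73, 46.45]": 2202
    missing: 16398

# Reported associations: per-bin positive-outcome counts k over bin totals n.
# printed_chi_square is the value reported alongside each association.
associations:
  - id: sex_ed
    outcome: ed
    feature: Sex
    bins: [female, male]
    positive: [15587, 10743]
    totals: [89531, 67875]
    printed_chi_square: 69.4
  - id: race_ed
    outcome: ed
    feature: Race
    bins: [Caucasian, African American]
    positive: [9304, 3137]
    totals: [78418, 28977]
    printed_chi_square: 22.3
  - id: age_ed
    outcome: ed
    feature: AgeStudyStart
    bins: ["<5", "5-17", "18-44", "45-64", "65-89"]
    positive: [914, 2576, 4655, 8822, 9365]
    totals: [5638, 20071, 35777, 51495, 44429]
    printed_chi_square: 1245.5
  - id: density_ed
    outcome: ed
    feature: EstResidentialDensity
    bins: [rural, urban cluster]
    positive: [18739, 7155]
    totals: [95632, 41798]
    printed_chi_square: 116.7
  - id: insurance_ed
    outcome: ed
    feature: EstProbabilityNoHealthIns
    bins: ["[0, 0.0637]", "(0.0637, 0.1121]", "(0.1121, 0.1644]", "(0.1644, 0.5548]"]
    positive: [5681, 6325, 6878, 7000]
    totals: [34500, 34313, 34340, 34201]
    printed_chi_square: 221.7
  - id: income_ed
    outcome: ed
    feature: EstHouseholdIncome
    bins: ["[7470, 36635]", "(36635, 46750]", "(46750, 59566]", "(59566, 78355]",
           "(78355, 250001]"]
    positive: [5847, 5553, 5127, 4872, 3898]
    totals: [26967, 27081, 26843, 26968, 26955]
    printed_chi_square: 542.5
  - id: roadway_ed
    outcome: ed
    feature: MajorRoadwayHighwayExposure
    bins: ["0-49", "50-99", "100-149", "150-199", "200-249", ">=250"]
    positive: [3516, 1800, 2021, 1850, 1607, 15529]
    totals: [17485, 9754, 10244, 9398, 8477, 85989]
    printed_chi_square: 59.6
  - id: pm25_ed
    outcome: ed
    feature: AvgDailyPM25Exposure
    bins: ["[3.27, 6.3]", "(6.3, 7.81]", "(7.81, 10.83]"]
    positive: [300, 1017, 24975]
    totals: [2170, 6636, 132206]
    printed_chi_square: 86.7
  - id: ozone_ed
    outcome: ed
    feature: MaxDailyOzoneExposure
    bins: ["[27.8, 39]", "(39, 42.73]", "(42.73, 46.45]"]
    positive: [21, 1749, 24522]
    totals: [236, 11372, 129404]
    printed_chi_square: 102.6
  - id: age_prednisone
    outcome: prednisone
    feature: AgeStudyStart
    bins: ["<5", "5-17", "18-44", "45-64", "65-89"]
    positive: [15, 1235, 3861, 6222, 5723]
    totals: [5638, 20071, 35777, 51495, 44429]
    printed_chi_square: 1382.8
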