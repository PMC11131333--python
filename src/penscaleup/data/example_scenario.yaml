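# Example scenario: national scale-up of DM/HTN care in Eswatini.
# All values shown are the package defaults; delete any block to use
# defaults implicitly.  Unknown keys are rejected.
seed: 1
out_dir: results
log_level: INFO

population:
  population_40plus: 223277
  dm_patients: {value: 14736, low: 12504, high: 16969}
  htn_patients: {value: 122133, low: 119990, high: 124365}
  comorbid_patients: {value: 13397, low: 11164, high: 15629}
  visits_per_patient_year: 6.52
  observed_visits_2022: 145764
  observed_unique_patients_2022: 34803

capacity:
  mode: CALIBRATED
  # annual DM/HTN visits one nurse can serve (back-calculated defaults)
  visits_per_nurse_year: {SOC: 821.0, INTERVENTION: 1443.0}
  working_days_per_year: 230

costs:
  nurse_salary_usd_year: 8077.0
  training_usd_per_nurse: 129.0
  med_dm_usd_patient_year: 7.71
  med_htn_usd_patient_year: 3.15
  diagnostics_usd_year: {SOC: 174900.0, INTERVENTION: 173310.0}
  szl_per_usd: 18.867

generator:
  enabled: false   # set true to also simulate and summarize a TMS study
  n_facilities: 28

uncertainty:
  n_draws: 10000
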