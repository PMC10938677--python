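# Exact composition of the packaged paper-mirror cohort: a synthetic 2015
# registry cohort whose category and subgroup cells reproduce the printed
# counts of the published ClinicalTrials.gov registry audit this package
# reimplements.  Counts not printed directly are plumbing denominators
# chosen to be consistent with the printed one-decimal percentages:
#   - n_phase1_total solves 50 / x = 2.5%
#   - n_control_latest_change_post_completion is 9.4% of the 5524 controls
#   - n_published_flips_concordant realizes ~6% concordance among the 113
#     published flips; n_published_controls_concordant ~61% of 177
n_total: 11908
n_originally_retrospective: 5759
n_retroactively_prospective: 235
n_retroactively_prospective_post_completion: 158
n_originally_retrospective_with_change: 1943
n_control_latest_change_post_completion: 519
n_phase1_total: 2000
n_phase1_retroactively_prospective: 50
n_published_retroactively_prospective: 113
n_published_claims_prospective: 12
n_published_flips_concordant: 7
n_published_controls: 177
n_published_controls_concordant: 108
registration_year: 2015
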