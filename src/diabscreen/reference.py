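"""Published 2010 US screening totals used as reference inputs.

These are the reported national totals for screening asymptomatic US adults
under the ADA and USPSTF guidelines in 2010 (screened populations, detectable
cases, primary-care contact), in thousands of people, together with the CDC
national prevalence totals for that year.  They serve as inputs to the
ratio/percentage operations — e.g. people screened per case detected, or the
share of detectable cases reachable during primary care visits — and as
realistic magnitudes for examples and documentation.
"""

# Screened populations (thousands), assuming the one-in-three annual
# screening fraction for low-risk adults 45+ under the ADA three-year cycle.
ADA_SCREENED_K = 86_292
USPSTF_SCREENED_K = 59_064

# Detectable cases among the screened populations (thousands).
ADA_DETECTED_DM_K = 4_639
USPSTF_DETECTED_DM_K = 3_735
ADA_DETECTED_PREDM_K = 33_927
USPSTF_DETECTED_PREDM_K = 24_407

# Adults with >= 1 primary care office visit among the eligible (thousands),
# and the detectable cases carried by that primary-care-reachable subset.
ADA_PRIMARY_CARE_K = 50_180
USPSTF_PRIMARY_CARE_K = 41_530
ADA_PRIMARY_CARE_DM_K = 3_083
USPSTF_PRIMARY_CARE_DM_K = 2_753

# CDC 2010 national totals (thousands): adults with undiagnosed diabetes and
# with (largely undetected) prediabetes.
NATIONAL_UNDIAG_DM_K = 7_000
NATIONAL_PREDM_K = 79_000
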