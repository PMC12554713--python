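# Default signal-positivity thresholds (conventional criteria for
# spontaneous-report disproportionality screening).
min_cases: 3          # minimum a (drug & event case count) to call any signal
ror_lo_gt: 1.0        # ROR 95% CI lower bound must exceed this
prr_ge: 2.0           # PRR threshold (with chi2_ge, both required)
chi2_ge: 4.0
ic025_gt: 0.0         # IC 2.5th-percentile lower bound
ebgm05_gt: 2.0        # EBGM posterior 5th percentile
alpha: 0.05           # familywise level for Bonferroni-adjusted p
bonferroni_m: auto    # auto = number of drug x event-set hypotheses in the run
rule: any             # any | all of the four methods
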