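# Default configuration for the bundled synthetic TRE alphabet.
# The flanks are the invariant amplicon ends (~30 nt of monotemplate
# sequence) that surround the variable promoter region.
flank5: ACGCGTTCGAACTGCAGGTCGACCATGGAA
flank3: TTCGAGCTCGGTACCCGGGGATCCTCTAGT

# Gel size-selection window for the promoter interior, in nucleotides.
min_len_nt: 200
max_len_nt: 500
mean_blocks: 35

# Candidate-selection thresholds.
min_baseline_freq: 0.001
min_fold_change: 1.25
min_timepoints_above: 2
cumulative_mass: 0.90
min_cpm_detect: 4.0
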