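# Demo run configuration: small two-chromosome population with the
# major-QTL founder effects planted on 2H.  All keys are optional; defaults
# are printed to the log at startup.
significance_threshold = 3.2
cofactor_exclusion_window = 10
rng_seed = 5
genotyping_error = 0.01
max_scan_iterations = 20
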