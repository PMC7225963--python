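# Published single-criterion validation counts: of all human caspase targets
# with complete metrics (n=2980) and of the 24-site reference set (cleavage
# sites with proven proapoptotic C-terminal fragments, in CASP2/3/6/7/8/9,
# PARP1/2, RIPK1, TRAF1, CAD), how many pass each criterion alone.
criterion	n_targets_pass	n_reference_pass	n_targets_total	n_reference_total
median_hd	2726	19	2980	24
coil_prevalence	1454	17	2980	24
hydro_prevalence	1457	16	2980	24
destab_fraction	554	4	2980	24
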