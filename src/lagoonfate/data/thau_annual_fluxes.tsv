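# Reference simulated annual interface fluxes for Thau lagoon, ng m-2 yr-1.
# Sign convention: positive = input to the water column.  Used to verify the
# additive structure of the budget reporter.
process	PeCDD	OCDD	TCDF	PeCDF	HxCDF
volatilization	-0.06	-0.06	-0.37	-0.31	-0.12
absorption	0.01	0.01	0.09	0.10	0.03
wet_deposition	0.07	7.73	0.05	0.19	0.59
dry_deposition	0.16	17.98	0.11	0.44	1.37
sediment_diffusion	0.01	1.75	0.04	0.05	0.07
settling	-0.24	-50.31	-0.47	-0.88	-1.35
resuspension	0.05	12.05	0.33	0.35	0.39
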