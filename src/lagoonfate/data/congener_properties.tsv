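# Default physicochemical constants of the modelled PCDD/F congener groups.
# STAND-IN literature values (see docs/methods.md); grouped labels (PeCDF,
# HxCDF) carry the arithmetic mean of member properties.  Units: molar_mass
# g/mol; log_kow_25 -; henry_25 Pa m3/mol at 298.15 K; dU_aw, dU_ow J/mol;
# deg_w, deg_s 1/s.
name	members	molar_mass	log_kow_25	henry_25	dU_aw	dU_ow	deg_w	deg_s
PeCDD	12378-PeCDD	354.5	7.40	1.00	55000	-25000	0	0
OCDD	OCDD	460.8	8.20	0.68	60000	-25000	0	0
TCDF	2378-TCDF	306.0	6.10	1.44	50000	-20000	0	0
PeCDF	12378-PeCDF,23478-PeCDF	340.4	6.50	0.50	52000	-22000	0	0
HxCDF	123478-HxCDF,123678-HxCDF,234678-HxCDF,123789-HxCDF	374.9	7.00	0.74	55000	-23000	0	0
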