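# Measured PCDD/F concentrations in the boundary compartments of Thau
# lagoon, ng m-3, used as default model forcing.  Values are kept in the
# notation of the source table (middle-dot powers of ten, thousands
# separators) and parsed by lagoonfate.forcing.read_boundary_concentrations.
congener	gas	air_particulate	rain	sediment	river	open_sea
PeCDD	1.68·10−6	3.37·10−6	0.67	256	4·10−3	5·10−4
OCDD	3.00·10−6	3.80·10−4	75.99	54,784	1,842	5.7·10−2
TCDF	2.96·10−6	2.43·10−6	0.49	1,484	40·10−3	5·10−4
PeCDF	3.97·10−6	9.25·10−6	1.85	1,587	59·10−3	1·10−3
HxCDF	1.79·10−6	2.95·10−5	5.90	2,611	143·10−3	4·10−3
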