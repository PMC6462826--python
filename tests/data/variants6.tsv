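variant_id	gene	activity	maf	SIFT	CADD	PROVEAN
v1	CYP2D6	0.05	0.0005	0.01	25.1	-6.5
v2	CYP2D6	0.32	0.002	.	18.0	-2.1
v3	CYP2C19	0.95	0.04	0.8	.	-0.5
v4	CYP2C19	1.10	.	0.45	12.3	-1.0
v5	SLCO1B1	0.00	0.0001	.	33.0	-9.2
v6	NAT1	0.70	0.15	0.2	9.9	-3.0
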