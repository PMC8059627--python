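# Published per-domain summary of disease missense mutations in human MYO7A:
# variant counts, mean unfolding propensity, and mean ddG (kcal/mol) per structural
# domain for the HGMD and ClinVar cohorts. "none" marks domains with no variants
# in that cohort. Cohorts: HGMD Professional 2019.4 and ClinVar exports for MYO7A.
domain	start	end	hgmd_n	hgmd_mean_propensity	hgmd_mean_ddg	clinvar_n	clinvar_mean_propensity	clinvar_mean_ddg
Motor domain	65	741	75	0.75	2.37	166	0.74	2.83
ATP-binding motif	158	165	4	0.825	2.27	3	0.62	0.52
Actin-binding	632	639	none	-	-	4	0.62	0.39
IQ1	745	765	2	0.8	1.49	6	0.75	1.29
IQ2	768	788	1	0.37	-0.32	4	0.72	1.14
IQ3	791	811	none	-	-	8	0.7	1.31
IQ4	814	834	1	0.97	2.02	10	0.76	1.08
IQ5	837	857	2	0.53	0.2	4	0.72	1.8
coiled coil	858	1016	3	0.89	2.06	8	0.72	1.3
single α-helix	858	935	2	0.97	2.27	21	0.68	1.8
MyTH-1	1017	1253	21	0.7	0.99	56	0.7	1.34
FERM-1	1258	1602	17	0.75	1.21	77	0.74	1.41
SH3	1603	1672	4	0.63	0.65	16	0.61	0.4
MyTH-2	1747	1896	13	0.82	3.1	42	0.71	2.25
FERM-2	1902	2205	24	0.64	0.97	68	0.72	1.98
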