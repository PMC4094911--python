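feature	mean	sd	block
bankssts	2.55	0.16	thickness
caudal_anterior_cingulate	2.75	0.22	thickness
caudal_middle_frontal	2.6	0.16	thickness
cuneus	1.9	0.14	thickness
entorhinal	3.35	0.3	thickness
fusiform	2.75	0.17	thickness
inferior_parietal	2.5	0.15	thickness
inferior_temporal	2.8	0.18	thickness
isthmus_cingulate	2.45	0.2	thickness
lateral_occipital	2.15	0.14	thickness
lateral_orbitofrontal	2.7	0.16	thickness
lingual	2.0	0.13	thickness
medial_orbitofrontal	2.45	0.17	thickness
middle_temporal	2.85	0.17	thickness
parahippocampal	2.8	0.28	thickness
paracentral	2.35	0.16	thickness
pars_opercularis	2.6	0.15	thickness
pars_orbitalis	2.7	0.19	thickness
pars_triangularis	2.5	0.15	thickness
pericalcarine	1.65	0.13	thickness
postcentral	2.05	0.14	thickness
posterior_cingulate	2.5	0.17	thickness
precentral	2.55	0.16	thickness
precuneus	2.35	0.15	thickness
rostral_anterior_cingulate	2.85	0.23	thickness
rostral_middle_frontal	2.4	0.15	thickness
superior_frontal	2.7	0.16	thickness
superior_parietal	2.2	0.14	thickness
superior_temporal	2.8	0.17	thickness
supramarginal	2.55	0.15	thickness
frontal_pole	2.8	0.24	thickness
temporal_pole	3.7	0.3	thickness
transverse_temporal	2.35	0.2	thickness
insula	3.0	0.2	thickness
third_ventricle	1100	180	volume
fourth_ventricle	1900	300	volume
brainstem	21000	2200	volume
cc_anterior	880	140	volume
cc_central	480	80	volume
cc_mid_anterior	450	75	volume
cc_mid_posterior	430	70	volume
cc_posterior	950	150	volume
csf	1000	160	volume
accumbens	580	90	volume
amygdala	1550	220	volume
caudate	3600	420	volume
cerebellum_cortex	52000	5200	volume
cerebellum_white_matter	13500	1900	volume
hippocampus	3900	480	volume
inferior_lateral_ventricle	900	150	volume
putamen	5100	600	volume
cerebral_cortex	230000	21000	volume
cerebral_white_matter	220000	24000	volume
lateral_ventricle	16000	2600	volume
pallidum	1750	240	volume
thalamus_proper	7000	750	volume
ventral_dc	3900	420	volume
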