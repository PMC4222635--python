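species	clade	is_mammal	sequenced_gb	genome_mean_gc_pct	n_domains	density_per_mb	mean_len_bp	median_len_bp	n_homogeneous	hom_frac_pct	hom_cov_pct	n_nonhomogeneous	nonhom_frac_pct	nonhom_cov_pct	n_isochoric	iso_frac_all_pct	iso_frac_hom_pct	iso_cov_pct
human	Primates	1	2.8	40.80	107571	38.7	25865	7808	74579	69.3	79.5	32992	30.7	20.5	1071	1.0	1.4	25.1
chimpanzee	Primates	1	2.8	40.70	107359	39	25637	7840	73172	68.2	79.0	34187	31.8	21.0	1052	1.0	1.4	25.1
orangutan	Primates	1	2.7	40.70	105688	38.8	25764	7936	72384	68.5	79.3	33304	31.5	20.7	1084	1.0	1.5	26.0
mouse	Muridae	1	2.6	41.80	67223	26.3	38060	9216	41783	62.2	78.7	25440	37.8	21.3	1312	2.0	3.1	33.7
rat	Muridae	1	2.5	41.90	63137	25.5	39233	9376	38945	61.7	79.0	24192	38.3	21.0	1317	2.1	3.4	33.7
horse	Laurasiatheria	1	2.0	41.10	112350	48.1	20787	7456	83169	74.0	85.6	29181	26.0	14.4	811	0.7	1.0	20.4
dog	Laurasiatheria	1	2.3	41.00	104885	45.3	22097	7744	73141	69.7	80.7	31744	30.3	19.3	721	0.7	1.0	19.7
cow	Laurasiatheria	1	2.2	41.70	96410	43.2	23144	7872	70850	73.5	85.2	25560	26.5	14.8	872	0.9	1.2	22.3
pig	Laurasiatheria	1	2.5	41.80	90881	38.6	25938	7744	64228	70.7	85.3	26653	29.3	14.7	1030	1.1	1.6	29.5
opossum	Marsupialia	1	3.4	37.70	107356	31.5	31788	7616	63393	59.0	80.2	43963	41.0	19.8	1705	1.6	2.7	37.5
chicken	Aves	0	1.0	41.30	39450	40.1	24965	9216	28141	71.3	82.4	11309	28.7	17.6	281	0.7	1.0	15.8
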