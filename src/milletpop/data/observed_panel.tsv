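# Observed per-locus summary statistics for the nine-locus Setaria panel.
# species: wild = green foxtail (S. viridis), cultivated = foxtail millet (S. italica).
# length/silent in bp (silent may be fractional); n = sampled haplotypes;
# pi/theta_w are per-site; rho is the per-locus population recombination estimate
# as printed (Na = not estimable); D/Dstar/Fstar are Tajima's and Fu & Li's tests.
species	locus	length	silent	n	S	pi	pi_silent	theta_w	theta_w_silent	tajima_D	fuli_Dstar	fuli_Fstar	rho	Rm	Hap	Hdiv
wild	DACP	1014	944.833	29	27	0.0062	0.0067	0.0068	0.0073	-0.3118	-0.4487	-0.4763	0.0002	0	13	0.877
wild	SIGT	732	681.833	29	10	0.0014	0.0015	0.0035	0.0037	-1.9503	-2.8589	-3.0169	0.0052	0	8	0.643
wild	ADTY	997	892.011	31	41	0.01	0.0111	0.0105	0.0112	-0.1808	-0.5215	-0.5215	0.0076	0	17	0.931
wild	PP2C	815	815	33	8	0.0021	0.0021	0.0024	0.0024	-0.3792	-0.6279	-0.6449	0.1034	1	8	0.799
wild	SPS1	716	716	31	10	0.0018	0.0018	0.0035	0.0035	-1.5505	-1.3113	-1.6212	0	0	7	0.452
wild	UPL	656	636.667	32	9	0.0024	0.0025	0.0034	0.0035	-0.8911	-1.0025	-1.1326	0.0027	0	6	0.609
wild	TIFIIF	569	521	29	9	0.0025	0.0027	0.004	0.0044	-1.1863	-0.9376	-1.1834	0.0253	0	9	0.717
wild	TRAN	440	195.187	32	14	0.0062	0.0063	0.0085	0.0085	-0.8844	-0.4649	-0.7027	1.1713	0	12	0.891
wild	MDEH	525	525	31	19	0.0042	0.0042	0.0091	0.0091	-1.8459	-2.6617	-2.8235	0.0315	0	14	0.819
cultivated	DACP	964	896	46	19	0.0035	0.0038	0.0045	0.0048	-0.6808	0.9081	0.4346	0	0	7	0.633
cultivated	SIGT	767	715.667	48	7	0.0012	0.0013	0.0021	0.0022	-1.0991	-0.3006	-0.6509	0	0	4	0.264
cultivated	ADTY	1005	900	50	6	0.0002	0.0003	0.0013	0.0015	-2.0897	-3.9817	-3.9678	0	0	3	0.079
cultivated	PP2C	760	760	47	2	0.0007	0.0007	0.0006	0.0006	0.3793	-0.8753	-0.5879	Na	0	3	0.528
cultivated	SPS1	695	695	46	4	0.0016	0.0016	0.0013	0.0013	0.476	1.0127	0.9907	0.0041	0	3	0.518
cultivated	UPL	761	734.333	48	6	0.0012	0.0012	0.0018	0.0018	-0.8501	-0.5283	-0.7377	0.0077	0	7	0.54
cultivated	TIFIIF	624	556.833	44	6	0.0019	0.002	0.0022	0.0017	-0.3342	-2.1726	-1.8723	0.0093	0	5	0.577
cultivated	TRAN	435	188.543	49	10	0.0042	0.0056	0.0052	0.0036	-0.5283	-0.4341	-0.5478	0.0219	1	9	0.743
cultivated	MDEH	549	549	43	15	0.0039	0.0039	0.0067	0.0067	-1.3336	0.7496	0.0648	0.2204	1	14	0.886
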