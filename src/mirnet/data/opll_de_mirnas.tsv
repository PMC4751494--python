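mirna	fold_change	p_value	fdr	status_opll_vs_pll	status_msc_osteo_vs_msc
hsa-miR-10a-3p	630.71	1.56E-38	7.90E-36	Up-regulated	Down-regulated
hsa-miR-10a-5p	460.77	1.02E-88	1.55E-85	Up-regulated	Not significant
hsa-miR-371a-3p	247.28	3.75E-16	1.90E-14	Up-regulated	Not significant
hsa-miR-516a-5p	104.58	6.44E-13	2.45E-11	Up-regulated	Down-regulated
hsa-miR-563	93.94	1.00E-28	2.31E-26	Up-regulated	Not significant
hsa-miR-554	80.34	3.31E-05	4.09E-04	Up-regulated	Not significant
hsa-miR-4716-3p	69.72	6.32E-24	6.41E-22	Up-regulated	Not significant
hsa-miR-888-5p	61.26	3.37E-08	7.32E-07	Up-regulated	Not significant
hsa-miR-564	53.81	1.24E-03	8.86E-03	Up-regulated	Not significant
hsa-miR-582-3p	49.66	4.68E-07	8.28E-06	Up-regulated	Not significant
hsa-miR-551b-3p	37.62	1.06E-28	2.31E-26	Up-regulated	Not significant
hsa-miR-1261	34.51	2.51E-18	1.74E-16	Up-regulated	Not significant
hsa-miR-623	34.50	6.25E-05	7.15E-04	Up-regulated	Up-regulated
hsa-miR-885-5p	33.32	7.46E-28	1.42E-25	Up-regulated	Not significant
hsa-miR-620	33.31	1.30E-04	1.33E-03	Up-regulated	Not significant
hsa-miR-662	30.46	3.29E-07	6.18E-06	Up-regulated	Up-regulated
hsa-miR-498	29.51	5.37E-04	4.25E-03	Up-regulated	Down-regulated
hsa-miR-885-3p	21.23	1.96E-08	4.45E-07	Up-regulated	Not significant
hsa-miR-582-5p	20.19	2.78E-15	1.24E-13	Up-regulated	Down-regulated
hsa-miR-95-3p	19.27	9.14E-07	1.53E-05	Up-regulated	Down-regulated
hsa-miR-195-3p	17.32	1.82E-16	1.03E-14	Up-regulated	Not significant
hsa-miR-520d-3p	13.97	5.84E-06	8.87E-05	Up-regulated	Not significant
hsa-miR-657	13.27	6.66E-05	7.39E-04	Up-regulated	Down-regulated
hsa-miR-135a-5p	12.18	1.40E-04	1.39E-03	Up-regulated	Down-regulated
hsa-miR-526b-5p	11.33	6.40E-05	7.19E-04	Up-regulated	Down-regulated
hsa-miR-10b-5p	11.22	2.14E-22	2.03E-20	Up-regulated	Not significant
hsa-miR-204-5p	10.08	2.90E-19	2.10E-17	Up-regulated	Not significant
hsa-miR-622	9.92	1.97E-04	1.87E-03	Up-regulated	Not significant
hsa-miR-302a-5p	9.70	9.01E-05	9.60E-04	Up-regulated	Not significant
hsa-miR-569	8.58	3.17E-04	2.85E-03	Up-regulated	Not significant
hsa-miR-507	8.49	8.03E-04	6.07E-03	Up-regulated	Not significant
hsa-miR-210-3p	8.11	1.06E-17	6.73E-16	Up-regulated	Not significant
hsa-miR-516b-5p	7.67	1.00E-03	7.45E-03	Up-regulated	Not significant
hsa-miR-335-3p	6.72	2.38E-05	3.17E-04	Up-regulated	Down-regulated
hsa-miR-124-3p	6.37	9.11E-13	3.38E-11	Up-regulated	Down-regulated
hsa-miR-133a-3p	5.61	2.07E-04	1.95E-03	Up-regulated	Not significant
hsa-miR-147b	5.26	4.63E-07	8.28E-06	Up-regulated	Not significant
hsa-miR-548b-3p	4.81	1.25E-03	8.87E-03	Up-regulated	Down-regulated
hsa-miR-551a	4.61	6.44E-05	7.19E-04	Up-regulated	Down-regulated
hsa-miR-675-5p	4.53	9.09E-05	9.60E-04	Up-regulated	Not significant
hsa-miR-146a-5p	4.39	2.70E-10	7.61E-09	Up-regulated	Down-regulated
hsa-miR-483-5p	4.30	6.66E-07	1.15E-05	Up-regulated	Not significant
hsa-miR-335-5p	4.03	3.66E-09	9.44E-08	Up-regulated	Not significant
hsa-miR-628-3p	3.76	1.10E-03	8.05E-03	Up-regulated	Not significant
hsa-miR-181a-2-3p	3.70	2.07E-05	2.84E-04	Up-regulated	Not significant
hsa-miR-181a-5p	3.32	4.67E-05	5.54E-04	Up-regulated	Not significant
hsa-miR-10b-3p	3.30	1.35E-03	9.52E-03	Up-regulated	Not significant
hsa-miR-23b-3p	2.74	3.37E-05	4.10E-04	Up-regulated	Not significant
hsa-miR-137	2.71	4.66E-04	3.85E-03	Up-regulated	Not significant
hsa-miR-148a-3p	2.18	1.33E-03	9.41E-03	Up-regulated	Not significant
hsa-miR-423-3p	0.50	8.57E-04	6.42E-03	Down-regulated	Not significant
hsa-miR-4521	0.49	3.34E-04	2.93E-03	Down-regulated	Not significant
hsa-miR-29a-5p	0.49	7.30E-04	5.57E-03	Down-regulated	Not significant
hsa-miR-199b-3p	0.48	4.91E-04	3.95E-03	Down-regulated	Not significant
hsa-miR-23a-5p	0.47	1.43E-03	9.94E-03	Down-regulated	Not significant
hsa-miR-31-3p	0.47	4.77E-04	3.89E-03	Down-regulated	Not significant
hsa-miR-324-3p	0.46	4.94E-04	3.95E-03	Down-regulated	Not significant
hsa-miR-16-2-3p	0.45	6.70E-04	5.17E-03	Down-regulated	Not significant
hsa-miR-149-5p	0.43	4.52E-04	3.76E-03	Down-regulated	Not significant
hsa-miR-330-3p	0.40	4.93E-04	3.95E-03	Down-regulated	Not significant
hsa-miR-31-5p	0.39	3.08E-05	3.84E-04	Down-regulated	Not significant
hsa-miR-887-3p	0.39	1.66E-04	1.62E-03	Down-regulated	Not significant
hsa-miR-337-5p	0.39	5.29E-05	6.14E-04	Down-regulated	Not significant
hsa-miR-708-5p	0.38	2.95E-05	3.77E-04	Down-regulated	Up-regulated
hsa-miR-625-3p	0.36	1.68E-05	2.39E-04	Down-regulated	Up-regulated
hsa-miR-34b-5p	0.35	2.65E-06	4.14E-05	Down-regulated	Not significant
hsa-miR-18a-5p	0.34	2.94E-06	4.57E-05	Down-regulated	Not significant
hsa-miR-130a-5p	0.33	7.66E-05	8.31E-04	Down-regulated	Down-regulated
hsa-miR-15b-3p	0.33	1.09E-05	1.57E-04	Down-regulated	Down-regulated
hsa-miR-34c-5p	0.32	4.01E-07	7.34E-06	Down-regulated	Not significant
hsa-miR-486-3p	0.31	4.78E-04	3.89E-03	Down-regulated	Not significant
hsa-miR-625-5p	0.31	1.52E-06	2.46E-05	Down-regulated	Not significant
hsa-miR-450b-5p	0.30	2.26E-04	2.12E-03	Down-regulated	Not significant
hsa-miR-222-5p	0.28	2.40E-08	5.36E-07	Down-regulated	Not significant
hsa-miR-542-3p	0.27	2.67E-07	5.20E-06	Down-regulated	Not significant
hsa-miR-146b-5p	0.23	1.80E-10	5.15E-09	Down-regulated	Not significant
hsa-miR-129-5p	0.22	1.40E-04	1.39E-03	Down-regulated	Not significant
hsa-miR-424-5p	0.20	4.68E-12	1.51E-10	Down-regulated	Not significant
hsa-miR-218-5p	0.19	1.86E-12	6.43E-11	Down-regulated	Not significant
hsa-miR-1246	0.19	1.99E-05	2.79E-04	Down-regulated	Not significant
hsa-miR-29b-1-5p	0.19	2.08E-13	8.09E-12	Down-regulated	Not significant
hsa-miR-132-3p	0.16	5.99E-14	2.40E-12	Down-regulated	Not significant
hsa-miR-196a-5p	0.16	3.90E-14	1.60E-12	Down-regulated	Not significant
hsa-miR-132-5p	0.15	7.67E-12	2.38E-10	Down-regulated	Not significant
hsa-miR-218-1-3p	0.15	1.20E-12	4.24E-11	Down-regulated	Not significant
hsa-miR-503-5p	0.15	2.56E-16	1.34E-14	Down-regulated	Not significant
hsa-miR-27a-5p	0.15	1.33E-14	5.62E-13	Down-regulated	Not significant
hsa-miR-490-3p	0.15	1.19E-08	2.78E-07	Down-regulated	Not significant
hsa-miR-424-3p	0.12	1.96E-15	9.04E-14	Down-regulated	Down-regulated
hsa-miR-196a-3p	0.12	3.26E-07	6.18E-06	Down-regulated	Not significant
hsa-miR-92a-2-5p	0.11	5.06E-05	5.92E-04	Down-regulated	Not significant
hsa-miR-2392	0.09	6.37E-05	7.19E-04	Down-regulated	Not significant
hsa-miR-490-5p	0.08	6.03E-04	4.73E-03	Down-regulated	Not significant
hsa-miR-196b-5p	0.07	1.80E-26	2.49E-24	Down-regulated	Not significant
hsa-miR-212-3p	0.07	1.20E-19	9.12E-18	Down-regulated	Not significant
hsa-miR-129-2-3p	0.05	5.26E-22	4.70E-20	Down-regulated	Not significant
hsa-miR-4461	0.05	1.14E-04	1.19E-03	Down-regulated	Not significant
hsa-miR-199b-5p	0.04	9.77E-22	8.25E-20	Down-regulated	Not significant
hsa-miR-378b	0.02	8.08E-08	1.64E-06	Down-regulated	Not significant
hsa-miR-1973	0.01	3.45E-04	2.98E-03	Down-regulated	Not significant
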