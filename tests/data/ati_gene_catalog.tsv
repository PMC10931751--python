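gene_code	gene_name	allele_count	main_r2_pct	gxe_r2_pct
gATI.1.1	Glyma01g02580	2	1.32	
gATI.1.2	Glyma01g04515	3	0.09	
gATI.1.3	Glyma01g22861	2	0.19	
gATI.1.4	Glyma01g30320	2	0.28	
gATI.1.5	Glyma01g36070	2	1.69	
gATI.2.1	Glyma02g00280	3	0.05	0.04
gATI.2.2	Glyma02g05640	3	0.08	
gATI.2.3	Glyma02g06730	5	3.48	0.07
gATI.2.4	Glyma02g08790	2	0.03	
gATI.2.5	Glyma02g09130	3	0.70	
gATI.2.6	Glyma02g09240	3	0.41	
gATI.2.7	Glyma02g11151	4	0.78	0.08
gATI.2.8	Glyma02g11335	4	1.28	
gATI.2.9	Glyma02g14175	2	0.12	
gATI.2.10	Glyma02g15470	3	0.28	
gATI.2.11	Glyma02g16850	3	0.39	
gATI.2.12	Glyma02g37010	2	0.05	
gATI.2.13	Glyma02g38673	3	0.19	
gATI.2.14	Glyma02g40220	3	0.06	
gATI.2.15	Glyma02g44350	2	0.24	
gATI.3.1	Glyma03g07890	2	0.74	
gATI.3.2	Glyma03g27770	2	2.23	
gATI.3.3	Glyma03g30270	4	2.14	0.04
gATI.3.4	Glyma03g36720	2		0.04
gATI.3.5	Glyma03g37221	2	0.33	0.08
gATI.4.1	Glyma04g10720	2	2.00	
gATI.4.2	Glyma04g43300	2	2.88	
gATI.5.1	Glyma05g19630	2	0.02	0.02
gATI.5.2	Glyma05g24760	3	0.09	
gATI.5.3	Glyma05g27300	2	0.94	
gATI.5.4	Glyma05g27690	5	0.20	0.08
gATI.5.5	Glyma05g32890	4	0.81	
gATI.6.1	Glyma06g01490	2	0.49	0.03
gATI.6.2	Glyma06g05300	3	1.82	
gATI.6.3	Glyma06g07980	3	4.66	
gATI.6.4	Glyma06g17410	2	0.08	
gATI.6.5	Glyma06g19756	2	0.20	
gATI.6.6	Glyma06g47010	4	0.14	
gATI.7.1	Glyma07g00400	4	0.73	
gATI.7.2	Glyma07g05620	4	2.45	0.03
gATI.7.3	Glyma07g06640	2	0.10	
gATI.7.4	Glyma07g07360	6	0.12	0.05
gATI.7.5	Glyma07g08290	2		0.05
gATI.7.6	Glyma07g10280	2	0.08	
gATI.7.7	Glyma07g14234	2	0.06	
gATI.7.8	Glyma07g31130	3	1.48	0.12
gATI.7.9	Glyma07g37810	2	0.16	
gATI.7.10	Glyma07g38180	3	2.90	
gATI.8.1	Glyma08g04620	4	0.18	
gATI.8.2	Glyma08g10001	3	0.02	
gATI.8.3	Glyma08g18320	2	0.38	
gATI.8.4	Glyma08g42810	4	0.05	
gATI.8.5	Glyma08g45301	3	0.65	
gATI.8.6	Glyma08g45501	2	0.13	
gATI.8.7	Glyma08g45610	2	0.72	0.15
gATI.9.1	Glyma09g12180	3	0.03	
gATI.9.2	Glyma09g15860	2	0.03	
gATI.9.3	Glyma09g33220	4	2.52	0.05
gATI.9.4	Glyma09g40690	3	0.68	
gATI.9.5	Glyma09g41821	3	0.38	0.03
gATI.10.1	Glyma10g06480	2	0.08	
gATI.10.2	Glyma10g06600	2	0.80	
gATI.10.3	Glyma10g07601	2	1.32	
gATI.10.4	Glyma10g14620	2	0.06	
gATI.10.5	Glyma10g30100	3	0.75	0.04
gATI.10.6	Glyma10g30320	2	0.27	
gATI.10.7	Glyma10g31560	2	1.32	0.02
gATI.10.8	Glyma10g37420	2	0.56	0.04
gATI.11.1	Glyma11g01253	3	0.05	
gATI.11.2	Glyma11g03580	2	0.11	
gATI.11.3	Glyma11g07830	4	0.71	
gATI.11.4	Glyma11g15140	2	0.01	0.05
gATI.11.5	Glyma11g27510	2	0.1	
gATI.12.1	Glyma12g03180	3	0.10	
gATI.12.2	Glyma12g08010	2	0.26	
gATI.12.3	Glyma12g30080	3	0.24	
gATI.13.1	Glyma13g00490	3	0.38	0.04
gATI.13.2	Glyma13g01900	2	0.04	
gATI.13.3	Glyma13g23910	3	0.64	
gATI.13.4	Glyma13g29225	3	0.12	
gATI.13.5	Glyma13g29360	2	0.45	0.02
gATI.13.6	Glyma13g29520	2	0.04	
gATI.13.7	Glyma13g40690	2	1.03	
gATI.13.8	Glyma13g42650	3	0.24	0.04
gATI.14.1	Glyma14g04260	3	0.14	
gATI.14.2	Glyma14g10780	7	0.98	
gATI.14.3	Glyma14g20110	2	0.31	
gATI.14.4	Glyma14g36130	2	0.25	
gATI.14.5	Glyma14g37280	3	2.84	0.05
gATI.14.6	Glyma14g38720	2	0.05	
gATI.15.1	Glyma15g02310	2	0.35	
gATI.15.2	Glyma15g04006	3	0.32	
gATI.15.3	Glyma15g07590	3	0.33	
gATI.15.4	Glyma15g16830	2	0.03	
gATI.15.5	Glyma15g19900	2		0.03
gATI.15.6	Glyma15g27480	5	0.36	
gATI.15.7	Glyma15g27750	2	0.37	
gATI.15.8	Glyma15g32540	2		0.03
gATI.16.1	Glyma16g08960	2	1.43	
gATI.16.2	Glyma16g28270	3	0.91	
gATI.16.3	Glyma16g32650	5	0.89	
gATI.16.4	Glyma16g33831	4	0.10	
gATI.17.1	Glyma17g07120	3	1.66	
gATI.17.2	Glyma17g08230	2	0.95	
gATI.17.3	Glyma17g10650	4	0.39	
gATI.17.4	Glyma17g15720	2	0.03	
gATI.17.5	Glyma17g16831	3	0.11	0.11
gATI.17.6	Glyma17g33020	2	0.09	
gATI.17.7	Glyma17g33930	2	2.56	
gATI.17.8	Glyma17g36130	2	1.46	0.08
gATI.18.1	Glyma18g01490	2	2.71	
gATI.18.2	Glyma18g03930	2		0.02
gATI.18.3	Glyma18g03975	2	0.68	
gATI.18.4	Glyma18g04870	2	0.35	
gATI.18.5	Glyma18g11512	4	0.15	
gATI.18.6	Glyma18g15001	3	0.03	0.09
gATI.18.7	Glyma18g16761	3	0.27	
gATI.18.8	Glyma18g16780	2	0.71	
gATI.18.9	Glyma18g28130	2	3.00	
gATI.18.10	Glyma18g40780	3	1.71	
gATI.18.11	Glyma18g46101	3	2.62	
gATI.18.12	Glyma18g49450	2	0.12	
gATI.18.13	Glyma18g50670	4	0.17	0.04
gATI.18.14	Glyma18g53285	3	2.06	0.07
gATI.19.1	Glyma19g31900	4	1.28	
gATI.19.2	Glyma19g35820	2	0.78	
gATI.19.3	Glyma19g42710	2		0.04
gATI.19.4	Glyma19g43880	2	0.06	
gATI.20.1	Glyma20g01460	2	0.22	0.01
gATI.20.2	Glyma20g24740	5	0.95	0.06
gATI.20.3	Glyma20g30360	2	0.97	
gATI.20.4	Glyma20g30870	2	0.17	
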