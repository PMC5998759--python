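scale	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity	0.02	0.77	-1.04	-1.14	1.35	-0.80	0.26	1.81	-0.41	1.14	1.00	-0.77	-0.09	-1.10	-0.42	-0.97	-0.77	1.13	1.71	1.11
average_flexibility	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420
polarizability	0.046	0.128	0.105	0.151	0.290	0.000	0.230	0.186	0.219	0.186	0.221	0.134	0.131	0.180	0.291	0.062	0.108	0.140	0.409	0.298
free_energy_solution	-0.368	4.530	2.060	1.770	1.060	-0.525	0.000	0.791	0.000	1.070	0.656	0.000	-2.240	0.731	-1.030	-0.524	0.000	0.401	1.600	4.910
accessible_surface_area	115.0	135.0	150.0	190.0	210.0	75.0	195.0	175.0	200.0	170.0	185.0	160.0	145.0	180.0	225.0	115.0	140.0	155.0	255.0	230.0
residue_volume	52.6	68.3	68.4	84.7	113.9	36.3	91.9	102.0	105.1	102.0	97.7	75.7	73.6	89.7	109.1	54.9	71.2	85.1	135.4	116.2
steric_parameter	0.52	0.62	0.76	0.68	0.70	0.00	0.70	1.02	0.68	0.98	0.78	0.76	0.36	0.68	0.68	0.53	0.50	0.76	0.70	0.70
relative_mutability	100.0	20.0	106.0	102.0	41.0	49.0	66.0	96.0	56.0	40.0	94.0	134.0	56.0	93.0	65.0	120.0	97.0	74.0	18.0	41.0
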