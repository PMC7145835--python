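network	n_nodes	n_edges	mean_degree_centrality	mean_betweenness_centrality	degree_identity_holds
Antipsychotics	89	419	0.106	0.0157	1
Psychosis	486	1409	0.0119	0.00642	1
Psychosis-antipsychotics combined	570	1825	0.0112	0.00563	1
AD	1061	15691	0.0279	0.00167	1
AD-psychosis combined	1456	16989	0.0160	0.00158	1
Vitamin D	89	344	0.0869	0.018	0
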