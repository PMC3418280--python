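taxon	A. gerardogreeni	A. revillagigedi	A. clathrata	A. fulva	A. fistularis (CAL)	A. fistularis (BER)	A. fistularis (BAH)	A. archeri	A. cauliformis	A. insularis
A. gerardogreeni	0.000	0.719	0.719	1.295	1.727	1.439	1.727	1.727	1.727	1.871
A. revillagigedi	0.719	0.000	0.288	1.439	1.295	1.583	1.871	1.871	1.871	2.014
A. clathrata	0.719	0.288	0.000	1.439	1.007	1.583	1.871	1.871	1.871	2.014
A. fulva	1.295	1.439	1.439	0.000	1.583	0.144	0.432	0.432	1.007	0.576
A. fistularis (CAL)	1.727	1.295	1.007	1.583	0.000	1.727	2.014	2.014	2.014	2.158
A. fistularis (BER)	1.439	1.583	1.583	0.144	1.727	0.000	0.576	0.288	1.151	0.719
A. fistularis (BAH)	1.727	1.871	1.871	0.432	2.014	0.576	0.000	0.863	1.439	1.007
A. archeri	1.727	1.871	1.871	0.432	2.014	0.288	0.863	0.000	1.439	1.007
A. cauliformis	1.727	1.871	1.871	1.007	2.014	1.151	1.439	1.439	0.000	1.583
A. insularis	1.871	2.014	2.014	0.576	2.158	0.719	1.007	1.007	1.583	0.000
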