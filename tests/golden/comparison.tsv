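condition	lambda_gw	pct_p05	pct_q05	pi1	n_tested	n_untested	best_pct_p05	best_pct_q05	best_pi1
none	1.053605189	0.15	0.025	0.25	40	0	False	False	False
known	0.9994914026	0.25	0.05	0.25	40	0	True	False	False
known+surrogates	1.071411049	0.175	0.075	0.3	40	0	False	True	True
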