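sample	best_match	dst	identity_ok	dr	flag
S001	S001	1	True	0	clean
S002	S002	1	True	0	clean
S003	S003	1	True	0	clean
S004	S004	0.867	True	0.421221865	contaminated
S005	S005	1	True	0	clean
S006	S006	1	True	0	clean
S007	S007	1	True	0	clean
S008	S008	1	True	0	clean
S009	S009	1	True	0	clean
S010	S010	1	True	0	clean
S011	S011	1	True	0	clean
S012	S012	1	True	0	clean
S013	S013	1	True	0	clean
S014	S014	1	True	0	clean
S015	S015	1	True	0	clean
S017	S017	1	True	0	clean
S018	S018	1	True	0	clean
S019	S019	1	True	0	clean
S020	S020	1	True	0	clean
S021	S021	1	True	0	clean
S022	S022	1	True	0	clean
S023	S023	1	True	0	clean
S024	S024	1	True	0	clean
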