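# SYNTHETIC example profile: trained on pairstitch-simulated
# reads (scripts/train_example_profile.py), not on instrument
# data. Binned qualities 27/31/34/37/40, shared-error rate 1e-3,
# seed 301, 1275740 overlap columns.
# table: mismatch
27	28	29	30	31	32	33	34	35	36	37	38	39	40
27	2	2	2	2	2	2	2	2	2	3	4	6	7	8
28	2	2	2	2	2	2	2	2	2	2	2	4	5	6
29	2	2	2	2	2	2	2	2	2	2	2	2	3	5
30	2	2	2	2	2	2	2	2	2	2	2	2	2	3
31	2	2	2	2	2	2	2	2	2	2	2	2	2	2
32	2	2	2	2	2	2	2	2	2	2	2	2	2	2
33	2	2	2	2	2	2	2	2	2	2	2	2	2	2
34	2	2	2	2	2	2	2	2	2	2	2	2	2	2
35	2	2	2	2	2	2	2	2	2	2	2	2	2	2
36	2	2	2	2	2	2	2	2	2	2	2	2	2	2
37	2	2	2	2	2	2	2	2	2	2	2	2	2	2
38	2	2	2	2	2	2	2	2	2	2	2	2	2	2
39	3	2	2	2	2	2	2	2	2	2	2	2	2	2
40	4	4	4	3	3	2	2	2	2	2	2	2	2	2
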