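# SYNTHETIC example profile: trained on pairstitch-simulated
# reads (scripts/train_example_profile.py), not on instrument
# data. Binned qualities 27/31/34/37/40, shared-error rate 1e-3,
# seed 301, 1275740 overlap columns.
# table: match
27	28	29	30	31	32	33	34	35	36	37	38	39	40
27	40	40	40	40	40	40	40	40	40	40	40	40	40	40
28	40	40	40	40	40	40	40	40	40	40	40	40	40	40
29	40	40	40	40	40	40	40	40	40	40	40	40	40	40
30	40	40	40	40	40	40	40	40	40	40	40	40	40	40
31	40	40	40	40	40	40	40	40	40	40	40	40	40	40
32	40	40	40	40	40	40	40	40	40	40	40	40	40	40
33	40	40	40	40	40	40	40	40	40	40	40	40	40	40
34	40	40	40	40	40	40	40	40	40	40	40	40	40	40
35	40	40	40	40	40	40	40	40	40	40	40	40	40	40
36	40	40	40	40	40	40	40	40	40	40	40	40	40	40
37	40	40	40	40	40	40	40	40	40	40	40	40	40	40
38	40	40	40	40	40	40	40	40	40	40	40	40	40	40
39	40	40	40	40	40	40	40	40	40	40	40	40	40	40
40	40	40	40	40	40	40	40	40	40	40	40	40	40	40
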