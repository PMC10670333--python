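viral_gene	average_rank
E3L	30.1
E9L	33.3
I3L	34.1
I4L	34.8
B8R	35.1
H5R	35.9
O1L	37.5
D1R	38.6
F4L	39.6
J6R	39.7
A12L	40.2
C4L	41.2
B2R	42.9
CSN3	43.4
F1L	44.2
D13L	44.4
A3L	44.6
D5R	44.6
A10L	46.0
A37R	46.5
A24R	47.9
F12L	48.3
A46R	48.4
A35R	49.4
M1L	50.2
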