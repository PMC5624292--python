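	FR1	FR2	FR3	FR4	FR5
FR1	0.0	0.022	0.091	0.096	0.038
FR2	0.022	0.0	0.049	0.062	0.027
FR3	0.091	0.049	0.0	0.030	0.099
FR4	0.096	0.062	0.030	0.0	0.085
FR5	0.038	0.027	0.099	0.085	0.0
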