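# Hypnotic response to intravenous anesthetics and their mixtures.
# Doses in mg/kg; effect is the fraction of subjects hypnotised (0 = none, 1 = all).
# Blank doses in the source table are zeros. Single-drug series, three binary
# fixed-ratio rays, and one ternary ray.
midazolam,propofol,alfentanil,effect
0.1,0,0,0.2
0.125,0,0,0.3
0.15,0,0,0.5
0.175,0,0,0.8
0.2,0,0,0.8
0,0.7,0,0.1
0,1.0,0,0.3
0,1.3,0,0.9
0,1.6,0,1
0,1.9,0,1
0,2.2,0,1
0,2.5,0,1
0,0,0.05,0.1
0,0,0.075,0.3
0,0,0.1,0.5
0,0,0.125,0.9
0,0,0.15,1
0.03,0.21,0,0.2
0.04,0.29,0,0.4
0.05,0.36,0,0.5
0.065,0.46,0,0.8
0.085,0.60,0,1
0.1,0.71,0,1
0.13,0.92,0,1
0.17,1.2,0,1
0,0.25,0.025,0.1
0,0.31,0.031,0.3
0,0.40,0.040,0.4
0,0.50,0.049,0.8
0,0.63,0.061,0.9
0.035,0,0.025,0.4
0.044,0,0.031,0.7
0.056,0,0.04,0.9
0.07,0,0.049,0.9
0.085,0,0.061,1
0.023,0.17,0.016,0.3
0.03,0.21,0.021,0.6
0.037,0.26,0.026,0.8
0.047,0.33,0.032,0.9
0.059,0.42,0.041,1
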