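# Per-window-width Gaussian score distributions for coiled-coil (cc) and
# globular (glob) sequence, used in the two-Gaussian likelihood ratio
# P = G_cc / (G_cc + G_glob).  Calibrated for the propensity table shipped
# alongside (ideal hydrophobic-a/d heptads score ~1.9-2.0; globular sequence
# ~0.9); larger windows average more positions, hence smaller spreads.
width	cc_mean	cc_sd	glob_mean	glob_sd
14	1.80	0.24	0.92	0.26
21	1.80	0.20	0.91	0.22
28	1.80	0.17	0.90	0.19
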