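label,follow_up_months,beta,delta,adjusted_r_square
PARAGON-A,1,0.42,1.09,0.9884
PARAGON-A,6,0.45,1.23,0.9917
GUSTO-IIB,1,0.62,0.92,0.9245
GUSTO-IIB,6,0.54,1.09,0.9427
Mean PARAGON-A & GUSTO-IIB,1,0.50,1.01,0.9615
Mean PARAGON-A & GUSTO-IIB,6,0.49,1.16,0.9734
Hyde,12,0.54,1.56,0.9844
Hyde,48,0.48,1.79,0.9477
Average curve,,0.46,1.28,0.9959
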