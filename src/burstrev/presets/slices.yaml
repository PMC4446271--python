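# Acute hippocampal slice (CA3/CA1 pyramidal cells, Schaffer stimulation).
tau: 0.01     # s
t_f: 1.3      # s
t_r: 20.0     # s
J: 2.06
K: 0.004
L: 0.037
X: 0.5
H: 50.0       # Hz
h_T: 10.0     # Hz
sigma: 2.0    # Hz
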