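# Hippocampal micro-culture ("islands") networks, 5-30 neurons.
tau: 0.01     # s
t_f: 1.3      # s
t_r: 2.0      # s
J: 1.98
K: 0.004      # per spike, with h in Hz and t in s
L: 0.0054
X: 0.5
H: 50.0       # Hz
h_T: 10.0     # Hz, burst-termination threshold
sigma: 2.0    # Hz, extracted firing-rate noise amplitude
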