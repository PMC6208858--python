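4
u 0.000 0.503 0.551 0.753
v 0.503 0.000 0.259 0.593
x 0.551 0.259 0.000 0.551
y 0.753 0.593 0.551 0.000
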