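A
C
D
E
F
G
H
I
K
L
M
N
P
Q
R
S
T
V
W
Y
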