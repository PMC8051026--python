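C
c
N
n
O
o
S
s
P
p
B
b
F
Cl
Br
I
H
(
)
[
]
=
#
-
+
.
/
\
@
:
%
0
1
2
3
4
5
6
7
8
9
A
D
E
G
K
L
M
R
T
V
W
X
Y
Z
a
e
g
i
l
r
t
u
h
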