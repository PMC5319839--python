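label,row,col
_,2,2
e,2,3
t,1,2
a,1,3
o,3,2
i,3,3
n,2,1
s,2,4
r,1,1
h,1,4
l,3,1
d,3,4
c,0,2
u,0,3
m,4,2
f,4,3
p,0,1
g,0,4
w,2,0
y,2,5
b,4,1
v,4,4
k,1,0
x,1,5
j,3,0
q,3,5
z,0,0
<,0,5
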