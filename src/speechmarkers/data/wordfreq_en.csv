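word,frequency
the,0.0539
and,0.0268
a,0.0214
to,0.0209
of,0.0178
is,0.0145
in,0.0110
it,0.0102
he,0.0089
that,0.0087
she,0.0072
was,0.0071
i,0.0069
on,0.0063
there,0.0045
with,0.0041
his,0.0040
they,0.0038
at,0.0033
are,0.0032
this,0.0030
her,0.0029
from,0.0026
out,0.0021
up,0.0020
him,0.0013
down,0.0012
over,0.0011
water,0.00055
little,0.00052
mother,0.00044
an,0.0032
has,0.0015
have,0.0031
not,0.0041
but,0.0035
what,0.0026
all,0.0023
were,0.0022
when,0.0021
we,0.0036
you,0.0058
off,0.0009
into,0.0010
going,0.0008
getting,0.0004
standing,0.00012
falling,0.00008
running,0.00025
washing,0.00006
drying,0.00002
reaching,0.00007
stealing,0.00003
watching,0.00022
taking,0.00030
looking,0.00045
boy,0.00032
girl,0.00035
woman,0.00045
lady,0.00018
man,0.00090
kitchen,0.00012
window,0.00018
curtain,0.00002
curtains,0.00002
cookie,0.00003
cookies,0.00004
biscuit,0.00001
jar,0.00003
stool,0.00001
bench,0.00004
ladder,0.00003
sink,0.00006
basin,0.00001
faucet,0.000006
tap,0.00006
plate,0.00007
plates,0.00004
dish,0.00004
dishes,0.00005
cup,0.00012
saucer,0.000004
towel,0.00003
rag,0.00001
cloth,0.00004
dishcloth,0.000002
cupboard,0.00002
cabinet,0.00005
shelf,0.00004
outside,0.00040
exterior,0.00002
garden,0.00012
yard,0.00010
outdoors,0.00002
driveway,0.00002
walkway,0.000008
brother,0.00020
sister,0.00020
son,0.00030
daughter,0.00020
lad,0.00002
mom,0.00020
wife,0.00025
overflowing,0.000008
wobbling,0.000002
spilling,0.000004
dry,0.00012
wet,0.00010
open,0.00050
full,0.00035
high,0.00060
clean,0.00018
messy,0.000015
sweet,0.00016
busy,0.00015
uh,0.00060
um,0.00050
here,0.00120
see,0.00110
stove,0.00002
floor,0.00020
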