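word,frequency
de,0.0520
la,0.0310
le,0.0290
et,0.0210
les,0.0190
des,0.0130
est,0.0120
un,0.0170
une,0.0130
il,0.0110
elle,0.0065
dans,0.0062
qui,0.0060
que,0.0085
pour,0.0055
sur,0.0040
avec,0.0035
pas,0.0042
au,0.0045
du,0.0052
se,0.0048
son,0.0035
sa,0.0030
ce,0.0050
je,0.0060
on,0.0045
ne,0.0050
y,0.0030
a,0.0090
en,0.0075
sont,0.0022
ils,0.0028
elles,0.0009
là,0.0018
euh,0.00050
voit,0.00030
regarde,0.00020
tombe,0.00015
vole,0.00008
prend,0.00040
lave,0.00006
sèche,0.00003
déborde,0.000015
coule,0.00005
vacille,0.000004
monte,0.00020
essuie,0.00002
garçon,0.00025
fille,0.00050
femme,0.00060
dame,0.00020
mère,0.00040
maman,0.00030
épouse,0.00006
frère,0.00025
fils,0.00035
sœur,0.00020
soeur,0.00012
fillette,0.00002
cuisine,0.00020
fenêtre,0.00018
rideau,0.00004
rideaux,0.00005
biscuit,0.00002
gâteau,0.00010
cookie,0.000008
bocal,0.000015
pot,0.00008
jarre,0.000004
boîte,0.00012
tabouret,0.000012
escabeau,0.000004
banc,0.00008
évier,0.000015
lavabo,0.00001
robinet,0.00002
assiette,0.00004
vaisselle,0.00002
plat,0.00012
tasse,0.00006
torchon,0.000008
chiffon,0.000008
linge,0.00004
placard,0.00003
armoire,0.00004
étagère,0.00002
extérieur,0.00010
dehors,0.00025
jardin,0.00030
allée,0.00008
eau,0.00060
petit,0.00090
petite,0.00070
ouvert,0.00012
ouverte,0.00008
plein,0.00020
pleine,0.00012
propre,0.00012
mouillé,0.00002
sec,0.00008
haut,0.00040
occupée,0.00002
débordé,0.000004
ici,0.00060
voilà,0.00030
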