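a
al
algo
algunas
algunos
ante
antes
aquel
aquella
aquellas
aquellos
aqui
aquí
asi
así
aunque
bien
cada
como
cómo
con
contra
cual
cuales
cuando
cuándo
de
del
desde
donde
dónde
dos
durante
e
el
él
ella
ellas
ellos
en
entre
era
eran
es
esa
esas
ese
eso
esos
esta
está
están
estaba
estaban
estas
este
esto
estos
fue
fueron
ha
había
habían
hace
hacen
han
hasta
hay
la
las
le
les
lo
los
más
mas
me
mi
mis
mientras
muy
nada
ni
no
nos
nosotros
nuestra
nuestras
nuestro
nuestros
o
os
otra
otras
otro
otros
para
pero
poco
por
porque
que
qué
quien
quién
se
sea
según
si
sí
sido
sin
sobre
son
su
sus
también
tan
tanto
te
tiene
tienen
toda
todavía
todo
todos
tras
tu
tus
un
una
unas
uno
unos
usted
vosotros
y
ya
yo
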