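# Spanish stopword list, v1 (one token per line; lines starting with # ignored)
de
la
que
el
en
y
a
los
del
se
las
por
un
para
con
una
su
al
lo
como
mas
pero
sus
le
ya
o
este
si
porque
esta
entre
cuando
muy
sin
sobre
tambien
hasta
hay
donde
quien
desde
todo
nos
durante
todos
uno
les
ni
contra
otros
ese
eso
ante
ellos
e
esto
antes
algunos
que
unos
otro
otras
otra
tanto
esa
estos
mucho
quienes
nada
muchos
cual
poco
ella
estar
estas
algunas
algo
nosotros
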