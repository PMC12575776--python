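# Bundled Spanish lexicon for the deterministic tagger: surface<TAB>pos<TAB>lemma
# Tagset: NC common noun, NP proper noun, ADJ adjective, PREP preposition,
# DET determiner, PRON pronoun, VERB verb, ADV adverb, CONJ conjunction, Z number, X other.
# Covers function words, frequent clinical verbs and irregular forms; open-class
# vocabulary not listed here falls back to the suffix rules / noun default.
de	PREP	de
del	PREP	de
a	PREP	a
al	PREP	a
en	PREP	en
por	PREP	por
con	PREP	con
para	PREP	para
sobre	PREP	sobre
entre	PREP	entre
desde	PREP	desde
hasta	PREP	hasta
tras	PREP	tras
según	PREP	según
durante	PREP	durante
sin	PREP	sin
no	ADV	no
ni	CONJ	ni
y	CONJ	y
e	CONJ	e
o	CONJ	o
u	CONJ	u
que	CONJ	que
como	CONJ	como
pero	CONJ	pero
si	CONJ	si
aunque	CONJ	aunque
porque	CONJ	porque
el	DET	el
la	DET	la
los	DET	los
las	DET	las
un	DET	un
una	DET	una
unos	DET	unos
unas	DET	unas
lo	PRON	lo
se	PRON	se
le	PRON	le
les	PRON	les
su	DET	su
sus	DET	sus
este	DET	este
esta	DET	esta
esto	PRON	esto
ese	DET	ese
esa	DET	esa
eso	PRON	eso
muy	ADV	muy
más	ADV	más
menos	ADV	menos
bien	ADV	bien
mal	ADV	mal
ya	ADV	ya
aún	ADV	aún
así	ADV	así
también	ADV	también
solo	ADV	solo
hoy	ADV	hoy
ayer	ADV	ayer
ahora	ADV	ahora
luego	ADV	luego
es	VERB	ser
son	VERB	ser
era	VERB	ser
fue	VERB	ser
ser	VERB	ser
siendo	VERB	ser
sido	VERB	ser
está	VERB	estar
están	VERB	estar
estaba	VERB	estar
estar	VERB	estar
estando	VERB	estar
hay	VERB	haber
ha	VERB	haber
han	VERB	haber
haber	VERB	haber
habido	VERB	haber
tiene	VERB	tener
tienen	VERB	tener
tener	VERB	tener
presenta	VERB	presentar
presentan	VERB	presentar
presentar	VERB	presentar
observa	VERB	observar
observan	VERB	observar
observar	VERB	observar
aprecia	VERB	apreciar
aprecian	VERB	apreciar
refiere	VERB	referir
refieren	VERB	referir
refiriendo	VERB	referir
acude	VERB	acudir
acuden	VERB	acudir
debe	VERB	deber
deben	VERB	deber
puede	VERB	poder
pueden	VERB	poder
podría	VERB	poder
corresponder	VERB	corresponder
corresponde	VERB	corresponder
descartar	VERB	descartar
descarta	VERB	descartar
descartan	VERB	descartar
descartando	VERB	descartar
descartarse	VERB	descartar
confirma	VERB	confirmar
confirman	VERB	confirmar
confirmar	VERB	confirmar
realiza	VERB	realizar
realizan	VERB	realizar
realizar	VERB	realizar
deriva	VERB	derivar
derivo	VERB	derivar
solicita	VERB	solicitar
solicito	VERB	solicitar
precisa	VERB	precisar
precisan	VERB	precisar
contacta	VERB	contactar
sospecha	NC	sospecha
sospechan	VERB	sospechar
aumentado	VERB	aumentar
hago	VERB	hacer
hace	VERB	hacer
hacer	VERB	hacer
indica	VERB	indicar
recomienda	VERB	recomendar
valora	VERB	valorar
impresiona	VERB	impresionar
niega	VERB	negar
pauta	NC	pauta
cita	NC	cita
leve	ADJ	leve
leves	ADJ	leve
grave	ADJ	grave
graves	ADJ	grave
normal	ADJ	normal
normales	ADJ	normal
anterior	ADJ	anterior
posterior	ADJ	posterior
abierta	ADJ	abierto
abiertas	ADJ	abierto
grasa	ADJ	graso
hialina	ADJ	hialino
ósea	ADJ	óseo
óseas	ADJ	óseo
óseo	ADJ	óseo
óseos	ADJ	óseo
tiroides	NC	tiroides
dosis	NC	dosis
padre	NC	padre
madre	NC	madre
abuelo	NC	abuelo
abuela	NC	abuela
hermano	NC	hermano
hermana	NC	hermana
tío	NC	tío
tía	NC	tía
primo	NC	primo
prima	NC	prima
familiar	NC	familiar
familiares	NC	familiar
paciente	NC	paciente
pacientes	NC	paciente
niño	NC	niño
niña	NC	niña
semana	NC	semana
semanas	NC	semana
mes	NC	mes
meses	NC	mes
año	NC	año
años	NC	año
día	NC	día
días	NC	día
vez	NC	vez
veces	NC	vez
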