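# Bundled Spanish trigger lexicon: phrase<TAB>TAG
# Tags: PREN pre-negation, POST post-negation, PSEU pseudo-negation (blocks),
# CONJ scope-terminating conjunction, FAM_PREN family pre-trigger, FAM_CONJ
# family scope terminator. Matching is longest-first over normalized tokens.
no	PREN
sin	PREN
ni	PREN
no hay	PREN
no hay signos de	PREN
sin signos de	PREN
sin evidencia	PREN
sin evidencia de	PREN
no evidencia de	PREN
no se observa	PREN
no se observan	PREN
no se aprecia	PREN
no se aprecian	PREN
no presenta	PREN
no presentan	PREN
se descarta	PREN
se descartan	PREN
descartando	PREN
ausencia de	PREN
niega	PREN
negativo para	PREN
descartado	POST
descartada	POST
debe ser descartado	POST
debe ser descartada	POST
no confirmado	POST
no confirmada	POST
negativo	POST
negativa	POST
ausente	POST
podría ser descartado	PSEU
podría ser descartada	PSEU
no se puede descartar	PSEU
no puede descartarse	PSEU
sin poder descartar	PSEU
no se descarta	PSEU
secundario a	CONJ
secundaria a	CONJ
debido a	CONJ
asociado a	CONJ
asociada a	CONJ
en contexto de	CONJ
aunque	CONJ
pero	CONJ
salvo	CONJ
excepto	CONJ
padre	FAM_PREN
madre	FAM_PREN
abuelo	FAM_PREN
abuela	FAM_PREN
hermano	FAM_PREN
hermana	FAM_PREN
tío	FAM_PREN
tía	FAM_PREN
primo	FAM_PREN
prima	FAM_PREN
familiar de	FAM_PREN
antecedentes familiares	FAM_PREN
antecedentes familiares de	FAM_PREN
historia familiar de	FAM_PREN
af	FAM_PREN
ahf	FAM_PREN
paciente	FAM_CONJ
el paciente	FAM_CONJ
la paciente	FAM_CONJ
el niño	FAM_CONJ
la niña	FAM_CONJ
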