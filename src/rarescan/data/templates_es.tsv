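# Sentence frames for the synthetic note generator: kind<TAB>template
# {X} is replaced by a disease expression, {KIN} by a kinship word that is a
# FAM_PREN trigger in the bundled lexicon. Negation frames place their trigger
# within the default scope window of 5 tokens.
affirm	Diagnóstico de {X}.
affirm	Se confirma {X}.
affirm	Paciente diagnosticado de {X} en seguimiento.
affirm	Control periódico por {X}.
affirm	Seguimiento de {X} en consulta.
affirm	Presenta {X} en tratamiento.
affirm	{X} confirmado por genética.
negated_pre	No hay signos de {X}.
negated_pre	Sin evidencia de {X}.
negated_pre	Se descarta {X}.
negated_pre	No se observan datos de {X}.
negated_post	{X} debe ser descartado.
negated_post	{X} no confirmado tras estudio.
family	{KIN} diagnosticado de {X}.
family	{KIN} con {X}.
family	{KIN} en seguimiento por {X}.
both	{KIN} sin evidencia de {X}.
both	{KIN} con {X} descartado.
filler	Exploración física normal.
filler	Peso 12 kg, talla 85 cm.
filler	Control en 6 meses.
filler	Vacunación al día.
filler	Tratamiento con ibuprofeno en pauta corta.
filler	Buena evolución clínica.
filler	Afebril, buen estado general.
filler	Se solicita analítica de control.
filler	Desarrollo psicomotor adecuado.
filler	Acude a revisión programada.
filler	Auscultación cardiopulmonar normal.
filler	Abdomen blando y depresible.
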