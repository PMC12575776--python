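# Bundled demonstration dictionary: nomenclature-style rows for the worked
# examples, the 19-disease reporting panel, and the diseases appearing in the
# negation/family examples. ORPHA codes for well-known entities follow the
# public Orphanet numbering where it is widely documented; codes in the 99xxx
# range are synthetic placeholders for fixture-only entries.
orpha_code	name	variants
249	Displasia fibrosa de hueso	Displasia ósea fibrosa
666	Osteogénesis imperfecta	Enfermedad de Lobstein|Enfermedad de Porak y Durante|Enfermedad de los huesos de cristal|OI|Osteopsatirosis
886	Síndrome de Usher	Retinosis pigmentaria-sordera|USH
79253	Fenilcetonuria leve	PKU leve|Variante de la PKU|Variante de la fenilcetonuria|mPKU
97120	Artrogriposis distal
1516	Craneosinostosis
93108	Displasia renal
355	Enfermedad de Gaucher	Deficiencia de glucocerebrosidasa
303	Epidermólisis bullosa distrófica
90291	Esclerodermia
805	Esclerosis tuberosa	Enfermedad de Bourneville
716	Fenilcetonuria	PKU|Deficiencia de fenilalanina hidroxilasa
586	Fibrosis quística	Mucoviscidosis|FQ
442	Hipotiroidismo congénito
791	Retinosis pigmentaria
72	Síndrome de Angelman
116	Síndrome de Beckwith-Wiedemann	Síndrome de Wiedemann-Beckwith|SBW
558	Síndrome de Marfan	MFS
739	Síndrome de Prader-Willi	SPW
881	Síndrome de Turner	Monosomía X
904	Síndrome de Williams	Síndrome de Williams-Beuren
3303	Tetralogía de Fallot	Síndrome de Fallot
99001	Leucomalacia periventricular
99002	Enfermedad neuromuscular
166	Enfermedad de Charcot	Enfermedad de Charcot-Marie-Tooth
99004	Malformación aórtica
99005	Miocardiopatía hipertrófica
226295	Hipotiroidismo primario congénito
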