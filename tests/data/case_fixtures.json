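{
  "_comment": "Worked-example fixtures: negated mentions, family mentions, and patient-classification cases. Cases flagged lexicon_sensitive depend on trigger phrases beyond the core quoted set; their expected label is the output under the BUNDLED trigger lexicon, stated here, not an externally fixed answer.",
  "negated_mentions": [
    {
      "text": "No se observan signos de hemorragia antigua de la matriz germinal ni leucomalacia periventricular",
      "orpha_code": "99001",
      "name": "Leucomalacia periventricular"
    },
    {
      "text": "RX de cráneo realizada por neurocirugía que según refiere no hay signos de craneosinostosis",
      "orpha_code": "1516",
      "name": "Craneosinostosis"
    },
    {
      "text": "Cuádriceps no presenta degeneración grasa por lo que no debe corresponder a una enfermedad neuromuscular",
      "orpha_code": "99002",
      "name": "Enfermedad neuromuscular"
    }
  ],
  "family_mentions": [
    {
      "text": "Padre nacido en ****, con enfermedad de Charcot",
      "orpha_code": "166",
      "name": "Enfermedad de Charcot"
    },
    {
      "text": "Acude la madre refiriendo que han intervenido al padre de una malformacion aortica",
      "orpha_code": "99004",
      "name": "Malformación aórtica"
    },
    {
      "text": "Abuelo diagnosticado de miocardiopatia hipertrofica",
      "orpha_code": "99005",
      "name": "Miocardiopatía hipertrófica"
    }
  ],
  "classification_cases": [
    {
      "case": 1,
      "text": "Esclerosis tuberosa comprobada por genética. Cojera. Exp: normal. Everolimus 5 mg.",
      "expected": "Esclerosis tuberosa",
      "lexicon_sensitive": false
    },
    {
      "case": 2,
      "text": "está siendo estudiado por AF de embarazo interrumpido a la 15 sem por Tetralogia de Fallot",
      "expected": "Tetralogía de Fallot",
      "lexicon_sensitive": true,
      "note": "The family trigger 'af' sits more than the scope window of 5 tokens before the mention, so under the bundled lexicon the mention stays individual and the disease is (wrongly, per the experts) predicted."
    },
    {
      "case": 3,
      "text": "No deformidad craneal congénita y desarrollo psicomotor normal. Aún así derivo para despistaje de craneosinostosis.",
      "expected": "Craneosinostosis",
      "lexicon_sensitive": false
    },
    {
      "case": 4,
      "text": "En tratamiento con eutirox.",
      "expected": "None",
      "lexicon_sensitive": false
    },
    {
      "case": 5,
      "text": "Se aprecian todas las suturas craneales abiertas asi como fontanela anterior, descartando craneosinostosis.",
      "expected": "None",
      "lexicon_sensitive": true,
      "note": "The bundled lexicon lists 'descartando' as a pre-negation, so the mention is negated and the patient classifies as None."
    },
    {
      "case": 6,
      "text": "resuelvo. Sd Marfan y conviviente vulnerable.",
      "expected": "None",
      "lexicon_sensitive": false
    },
    {
      "case": 7,
      "text": "23 en cariotipo compatible con S Williams.",
      "expected": "None",
      "lexicon_sensitive": false
    },
    {
      "case": 8,
      "text": "Diagnostico postnatal de T. Fallot",
      "expected": "None",
      "lexicon_sensitive": false
    },
    {
      "case": 9,
      "text": "Tratalogia de fallot pendiente de cirugia",
      "expected": "None",
      "lexicon_sensitive": false
    },
    {
      "case": 10,
      "text": "Sospechan esclerosis tuberosa no confirmada por derma ni RM; han aumentado dosis de depakine.",
      "expected": "None",
      "lexicon_sensitive": true,
      "note": "The bundled lexicon lists 'no confirmada' as a post-negation, so the mention is negated and the patient classifies as None."
    },
    {
      "case": 11,
      "text": "Gammagrafía tiroidea: tiroides ectópico sublingual. Levotroid 50: 1/2 / día. Hago receta de Eutirox 88.",
      "expected": "None",
      "lexicon_sensitive": false
    },
    {
      "case": 12,
      "text": "Pruebas metabólicas alteradas con sospecha de hipotiroidismo congénito. Se realiza nueva prueba del talón en el centro de salud. Pruebas metabólicas normales.",
      "expected": "Hipotiroidismo congénito",
      "lexicon_sensitive": false
    },
    {
      "case": 13,
      "text": "prematuridad, 31 semanas eg dg. al alta sd prader. willi dap, precisa sonda nasogástrica, enf. membrana hialina leve. Se contacta con enfermera de enlace.",
      "expected": "None",
      "lexicon_sensitive": false
    }
  ]
}
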