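{
  "_comment": "Synthetic Spanish polarity word lists for the default lexicon polarity scorer. Stand-in vocabulary for desk-scale experiments; real deployments should plug in a trained polarity model.",
  "positive": ["feliz", "genial", "gracias", "amor", "contento", "sonrisa", "bueno", "bien", "alegria", "esperanza", "bonito", "excelente"],
  "negative": ["triste", "llorar", "vacio", "miedo", "panico", "ansiedad", "depresion", "dolor", "odio", "fracaso", "morir", "angustia", "desesperanza", "deuda", "enfermo", "solo"]
}
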