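{
  "first_person": ["yo", "me", "mi", "mio", "estoy", "soy", "conmigo"],
  "suicide_explicit": ["quiero morir", "me quiero matar", "suicidarme", "no quiero vivir", "acabar con todo", "quitarme la vida", "desaparecer para siempre"],
  "suicide_methods": ["pastillas", "saltar al vacio", "cortarme las venas", "ahorcarme"],
  "self_harm": ["me corto", "hacerme dano", "autolesion", "herirme"],
  "self_loathing": ["me odio", "soy un fracaso", "no valgo nada", "soy una carga"],
  "depression": ["depresion", "triste", "llorar", "vacio", "sin ganas", "desesperanza"],
  "anxiety": ["ansiedad", "panico", "miedo", "no puedo respirar", "angustia"],
  "insomnia": ["no puedo dormir", "insomnio", "desvelado", "madrugada despierto"],
  "negations": ["no", "nunca", "nada", "jamas", "tampoco"],
  "feelings": ["siento", "sentir", "me siento", "sentimiento"],
  "social_support_lack": ["nadie me quiere", "estoy solo", "sin amigos", "nadie entiende"],
  "health": ["salud", "hospital", "medico", "enfermo", "dolor", "tratamiento"],
  "work": ["trabajo", "oficina", "jefe", "reunion", "proyecto", "empleo"],
  "money": ["dinero", "pagar", "banco", "sueldo", "precio", "deuda"],
  "news_media": ["noticia", "informe", "prevencion", "campana", "articulo", "entrevista"],
  "positive_emotion": ["feliz", "genial", "gracias", "amor", "contento", "sonrisa"]
}
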