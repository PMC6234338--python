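{
 "description": "Reduced (5-item) Morningness-Eveningness questionnaire scoring key. Each item lists the admissible scores for its response options; the chronotype total is the plain sum, spanning 4-25.",
 "items": [
  {"id": 1, "topic": "preferred rise time", "admissible": [1, 2, 3, 4, 5]},
  {"id": 2, "topic": "tiredness during first half hour after waking", "admissible": [1, 2, 3, 4]},
  {"id": 3, "topic": "time of evening fatigue", "admissible": [1, 2, 3, 4, 5]},
  {"id": 4, "topic": "time of day of feeling best", "admissible": [1, 2, 3, 4, 5]},
  {"id": 5, "topic": "self-rated morningness-eveningness type", "admissible": [0, 2, 4, 6]}
 ],
 "classes": [
  {"label": "definitely evening", "min": 4, "max": 7},
  {"label": "moderately evening", "min": 8, "max": 11},
  {"label": "neither", "min": 12, "max": 17},
  {"label": "moderately morning", "min": 18, "max": 21},
  {"label": "definitely morning", "min": 22, "max": 25}
 ]
}
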