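{
  "version": 1,
  "comment": "Command-sentence template inventory for the action-performing corpus generator. VP1 always denotes the first-EXECUTED action; a template with inversion=true places VP2 before VP1 on the surface (temporal inversion, as with 'before you ... please ...'). vp_shapes expand per action type: 'obj' actions are verb(object), 'loc' actions are verb(object, location).",
  "vp_shapes": {
    "base":    {"obj": "{V} the {O}",    "loc": "{V} the {O} on the {L}"},
    "bare":    {"obj": "{V} {O}",        "loc": "{V} {O} on the {L}"},
    "to":      {"obj": "{V} to the {O}", "loc": "{V} the {O} to the {L}"},
    "invloc":  {"obj": "{V} to the {O}", "loc": "{V} on the {L} the {O}"},
    "fronted": {"obj": "please {V} the {O}", "loc": "on the {L} {V} the {O}"}
  },
  "templates": [
    {"id": "ss-base",        "style": "simple",    "arity": 1, "surface": "{VP1}",                          "shapes": ["base"],         "inversion": false},
    {"id": "ss-bare",        "style": "simple",    "arity": 1, "surface": "{VP1}",                          "shapes": ["bare"],         "inversion": false},
    {"id": "es-please",      "style": "elaborate", "arity": 1, "surface": "please {VP1}",                   "shapes": ["base"],         "inversion": false},
    {"id": "es-marked",      "style": "elaborate", "arity": 1, "surface": "{VP1}",                          "shapes": ["invloc"],       "inversion": false},
    {"id": "es-fronted",     "style": "elaborate", "arity": 1, "surface": "{VP1}",                          "shapes": ["fronted"],      "inversion": false},
    {"id": "es-you",         "style": "elaborate", "arity": 1, "surface": "you {VP1}",                      "shapes": ["to"],           "inversion": false},
    {"id": "sd-then",        "style": "simple",    "arity": 2, "surface": "{VP1} then {VP2}",               "shapes": ["base", "base"], "inversion": false},
    {"id": "sd-andthen",     "style": "simple",    "arity": 2, "surface": "{VP1} and then {VP2}",           "shapes": ["base", "base"], "inversion": false},
    {"id": "sd-and",         "style": "simple",    "arity": 2, "surface": "{VP1} and {VP2}",                "shapes": ["base", "base"], "inversion": false},
    {"id": "sd-twice",       "style": "simple",    "arity": 2, "surface": "{V1} the {O1} twice",            "shapes": [],               "inversion": false, "repeat": true},
    {"id": "ed-before-inv",  "style": "elaborate", "arity": 2, "surface": "before you {VP2} please {VP1}",  "shapes": ["base", "base"], "inversion": true},
    {"id": "ed-before-chron","style": "elaborate", "arity": 2, "surface": "{VP1} before you {VP2}",         "shapes": ["base", "base"], "inversion": false},
    {"id": "ed-after-chron", "style": "elaborate", "arity": 2, "surface": "after you {VP1} {VP2}",          "shapes": ["base", "base"], "inversion": false},
    {"id": "ed-after-inv",   "style": "elaborate", "arity": 2, "surface": "{VP2} after you {VP1}",          "shapes": ["base", "base"], "inversion": true},
    {"id": "ed-marked",      "style": "elaborate", "arity": 2, "surface": "{VP1} and then {VP2}",           "shapes": ["invloc", "invloc"], "inversion": false},
    {"id": "ed-anaph-obj",   "style": "elaborate", "arity": 2, "surface": "{VP1} and then {V2} it",         "shapes": ["base"],         "inversion": false, "anaphora": true, "second_type": "obj"},
    {"id": "ed-anaph-loc",   "style": "elaborate", "arity": 2, "surface": "{VP1} then {V2} it to the {L2}", "shapes": ["base"],         "inversion": false, "anaphora": true, "second_type": "loc"},
    {"id": "ed-twotimes",    "style": "elaborate", "arity": 2, "surface": "{V1} the {O1} two times",        "shapes": [],               "inversion": false, "repeat": true}
  ]
}
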