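[
 {"unit_id": "boy", "surface_forms": ["boy", "brother", "little boy"], "relatedness": "related", "location": "left"},
 {"unit_id": "girl", "surface_forms": ["girl", "sister", "little girl"], "relatedness": "related", "location": "left"},
 {"unit_id": "woman", "surface_forms": ["woman", "mother", "mom", "lady"], "relatedness": "related", "location": "right"},
 {"unit_id": "cookie", "surface_forms": ["cookie", "cookies"], "relatedness": "related", "location": "left"},
 {"unit_id": "jar", "surface_forms": ["jar", "cookie jar"], "relatedness": "related", "location": "left"},
 {"unit_id": "stool", "surface_forms": ["stool", "ladder"], "relatedness": "related", "location": "left"},
 {"unit_id": "cupboard", "surface_forms": ["cupboard", "cabinet", "shelf"], "relatedness": "related", "location": "left"},
 {"unit_id": "falling", "surface_forms": ["falling", "fall", "tipping", "tipping over"], "relatedness": "related", "location": "left"},
 {"unit_id": "stealing", "surface_forms": ["stealing", "taking", "reaching", "grabbing"], "relatedness": "related", "location": "left"},
 {"unit_id": "sink", "surface_forms": ["sink", "basin"], "relatedness": "related", "location": "right"},
 {"unit_id": "water", "surface_forms": ["water"], "relatedness": "related", "location": "right"},
 {"unit_id": "overflowing", "surface_forms": ["overflowing", "overflow", "running over", "spilling"], "relatedness": "related", "location": "right"},
 {"unit_id": "dishes", "surface_forms": ["dishes", "dish", "plate", "plates"], "relatedness": "related", "location": "right"},
 {"unit_id": "drying", "surface_forms": ["drying", "washing", "wiping"], "relatedness": "related", "location": "right"},
 {"unit_id": "faucet", "surface_forms": ["faucet", "tap"], "relatedness": "related", "location": "right"},
 {"unit_id": "window", "surface_forms": ["window"], "relatedness": "related", "location": "right"},
 {"unit_id": "curtains", "surface_forms": ["curtains", "curtain", "drapes"], "relatedness": "related", "location": "right"},
 {"unit_id": "dog", "surface_forms": ["dog", "puppy"], "relatedness": "related", "location": "left"},
 {"unit_id": "kitchen", "surface_forms": ["kitchen"], "relatedness": "related", "location": "both"},
 {"unit_id": "family", "surface_forms": ["family"], "relatedness": "related", "location": "both"},
 {"unit_id": "floor", "surface_forms": ["floor"], "relatedness": "related", "location": "both"},
 {"unit_id": "garden", "surface_forms": ["garden", "yard"], "relatedness": "unrelated", "location": "right"},
 {"unit_id": "weather", "surface_forms": ["weather", "sunny day"], "relatedness": "unrelated", "location": "both"},
 {"unit_id": "house", "surface_forms": ["house", "home"], "relatedness": "unrelated", "location": "both"}
]
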