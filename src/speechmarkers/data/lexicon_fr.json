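{
  "language": "fr",
  "ius": [
    {"name": "boy", "keywords": ["garçon", "frère", "fils", "petit garçon"],
     "half": "left", "quadrant": "SW", "stripe": "center-left"},
    {"name": "girl", "keywords": ["fille", "sœur", "soeur", "fillette"],
     "half": "left", "quadrant": "SW", "stripe": "center-left"},
    {"name": "woman", "keywords": ["femme", "mère", "maman", "dame", "épouse"],
     "half": "right", "quadrant": "SE", "stripe": "center-right"},
    {"name": "kitchen", "keywords": ["cuisine"],
     "half": "right", "quadrant": "SE", "stripe": "center-right"},
    {"name": "exterior", "keywords": ["extérieur", "dehors", "jardin", "allée"],
     "half": "right", "quadrant": "NE", "stripe": "most-right"},
    {"name": "cookie", "keywords": ["biscuit", "gâteau", "cookie"],
     "half": "left", "quadrant": "NW", "stripe": "center-left"},
    {"name": "jar", "keywords": ["bocal", "pot", "jarre", "boîte à biscuits"],
     "half": "left", "quadrant": "NW", "stripe": "center-left"},
    {"name": "stool", "keywords": ["tabouret", "escabeau", "banc"],
     "half": "left", "quadrant": "SW", "stripe": "most-left"},
    {"name": "sink", "keywords": ["évier", "lavabo", "robinet"],
     "half": "right", "quadrant": "SE", "stripe": "center-right"},
    {"name": "plate", "keywords": ["assiette"],
     "half": "right", "quadrant": "SE", "stripe": "most-right"},
    {"name": "dishcloth", "keywords": ["torchon", "chiffon", "linge"],
     "half": "right", "quadrant": "SE", "stripe": "most-right"},
    {"name": "water", "keywords": ["eau"],
     "half": "right", "quadrant": "SE", "stripe": "most-right"},
    {"name": "window", "keywords": ["fenêtre"],
     "half": "right", "quadrant": "NE", "stripe": "most-right"},
    {"name": "cupboard", "keywords": ["placard", "armoire", "étagère"],
     "half": "left", "quadrant": "NW", "stripe": "most-left"},
    {"name": "dish", "keywords": ["vaisselle", "plat", "tasse"],
     "half": "right", "quadrant": "SE", "stripe": "center-right"},
    {"name": "curtain", "keywords": ["rideau"],
     "half": "right", "quadrant": "NE", "stripe": "most-right"}
  ]
}
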