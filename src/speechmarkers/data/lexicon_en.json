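{
  "language": "en",
  "ius": [
    {"name": "boy", "keywords": ["boy", "brother", "son", "lad"],
     "half": "left", "quadrant": "SW", "stripe": "center-left"},
    {"name": "girl", "keywords": ["girl", "sister", "daughter"],
     "half": "left", "quadrant": "SW", "stripe": "center-left"},
    {"name": "woman", "keywords": ["woman", "mother", "mom", "lady", "wife"],
     "half": "right", "quadrant": "SE", "stripe": "center-right"},
    {"name": "kitchen", "keywords": ["kitchen"],
     "half": "right", "quadrant": "SE", "stripe": "center-right"},
    {"name": "exterior", "keywords": ["outside", "exterior", "garden", "yard", "outdoors", "driveway", "walkway"],
     "half": "right", "quadrant": "NE", "stripe": "most-right"},
    {"name": "cookie", "keywords": ["cookie", "biscuit"],
     "half": "left", "quadrant": "NW", "stripe": "center-left"},
    {"name": "jar", "keywords": ["jar", "cookie jar"],
     "half": "left", "quadrant": "NW", "stripe": "center-left"},
    {"name": "stool", "keywords": ["stool", "bench", "ladder"],
     "half": "left", "quadrant": "SW", "stripe": "most-left"},
    {"name": "sink", "keywords": ["sink", "basin", "faucet", "tap"],
     "half": "right", "quadrant": "SE", "stripe": "center-right"},
    {"name": "plate", "keywords": ["plate"],
     "half": "right", "quadrant": "SE", "stripe": "most-right"},
    {"name": "dishcloth", "keywords": ["dishcloth", "dish cloth", "dish towel", "towel", "rag", "cloth"],
     "half": "right", "quadrant": "SE", "stripe": "most-right"},
    {"name": "water", "keywords": ["water"],
     "half": "right", "quadrant": "SE", "stripe": "most-right"},
    {"name": "window", "keywords": ["window"],
     "half": "right", "quadrant": "NE", "stripe": "most-right"},
    {"name": "cupboard", "keywords": ["cupboard", "cabinet", "shelf"],
     "half": "left", "quadrant": "NW", "stripe": "most-left"},
    {"name": "dish", "keywords": ["dish", "cup", "saucer"],
     "half": "right", "quadrant": "SE", "stripe": "center-right"},
    {"name": "curtain", "keywords": ["curtain", "drape"],
     "half": "right", "quadrant": "NE", "stripe": "most-right"}
  ]
}
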