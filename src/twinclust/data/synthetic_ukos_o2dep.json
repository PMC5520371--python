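{
 "_comment": "Synthetic stand-in covariate distribution for a preterm cohort (oxygen-dependence outcome model); not estimated from any real dataset.",
 "continuous": [
  "bweight",
  "gestage"
 ],
 "categorical": [
  "sex",
  "smoking"
 ],
 "profiles": [
  {
   "levels": {
    "sex": 0,
    "smoking": 0
   },
   "prob_singleton": 0.324,
   "prob_twin": 0.324
  },
  {
   "levels": {
    "sex": 0,
    "smoking": 1
   },
   "prob_singleton": 0.126,
   "prob_twin": 0.126
  },
  {
   "levels": {
    "sex": 1,
    "smoking": 0
   },
   "prob_singleton": 0.396,
   "prob_twin": 0.396
  },
  {
   "levels": {
    "sex": 1,
    "smoking": 1
   },
   "prob_singleton": 0.154,
   "prob_twin": 0.154
  }
 ],
 "mvn": {
  "sex=0|smoking=0": {
   "singleton": {
    "mean": [
     820.0,
     26.4
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002
     ],
     [
      123.20000000000002,
      1.9599999999999997
     ]
    ]
   },
   "twin_pair": {
    "mean": [
     770.0,
     26.299999999999997,
     770.0,
     26.299999999999997
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002,
      17920.0,
      100.46655961064856
     ],
     [
      123.20000000000002,
      1.9599999999999997,
      100.46655961064856,
      1.8619999999999994
     ],
     [
      17920.0,
      100.46655961064856,
      25600.0,
      123.20000000000002
     ],
     [
      100.46655961064856,
      1.8619999999999994,
      123.20000000000002,
      1.9599999999999997
     ]
    ]
   }
  },
  "sex=0|smoking=1": {
   "singleton": {
    "mean": [
     760.0,
     26.299999999999997
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002
     ],
     [
      123.20000000000002,
      1.9599999999999997
     ]
    ]
   },
   "twin_pair": {
    "mean": [
     710.0,
     26.199999999999996,
     710.0,
     26.199999999999996
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002,
      17920.0,
      100.46655961064856
     ],
     [
      123.20000000000002,
      1.9599999999999997,
      100.46655961064856,
      1.8619999999999994
     ],
     [
      17920.0,
      100.46655961064856,
      25600.0,
      123.20000000000002
     ],
     [
      100.46655961064856,
      1.8619999999999994,
      123.20000000000002,
      1.9599999999999997
     ]
    ]
   }
  },
  "sex=1|smoking=0": {
   "singleton": {
    "mean": [
     870.0,
     26.5
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002
     ],
     [
      123.20000000000002,
      1.9599999999999997
     ]
    ]
   },
   "twin_pair": {
    "mean": [
     820.0,
     26.4,
     820.0,
     26.4
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002,
      17920.0,
      100.46655961064856
     ],
     [
      123.20000000000002,
      1.9599999999999997,
      100.46655961064856,
      1.8619999999999994
     ],
     [
      17920.0,
      100.46655961064856,
      25600.0,
      123.20000000000002
     ],
     [
      100.46655961064856,
      1.8619999999999994,
      123.20000000000002,
      1.9599999999999997
     ]
    ]
   }
  },
  "sex=1|smoking=1": {
   "singleton": {
    "mean": [
     810.0,
     26.4
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002
     ],
     [
      123.20000000000002,
      1.9599999999999997
     ]
    ]
   },
   "twin_pair": {
    "mean": [
     760.0,
     26.299999999999997,
     760.0,
     26.299999999999997
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002,
      17920.0,
      100.46655961064856
     ],
     [
      123.20000000000002,
      1.9599999999999997,
      100.46655961064856,
      1.8619999999999994
     ],
     [
      17920.0,
      100.46655961064856,
      25600.0,
      123.20000000000002
     ],
     [
      100.46655961064856,
      1.8619999999999994,
      123.20000000000002,
      1.9599999999999997
     ]
    ]
   }
  }
 },
 "truncation": {}
}
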