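{
 "_comment": "Synthetic stand-in covariate distribution for a preterm cohort (death outcome model); not estimated from any real dataset.",
 "continuous": [
  "bweight",
  "gestage",
  "apgar"
 ],
 "categorical": [
  "sex"
 ],
 "profiles": [
  {
   "levels": {
    "sex": 0
   },
   "prob_singleton": 0.45,
   "prob_twin": 0.45
  },
  {
   "levels": {
    "sex": 1
   },
   "prob_singleton": 0.55,
   "prob_twin": 0.55
  }
 ],
 "mvn": {
  "sex=0": {
   "singleton": {
    "mean": [
     810.0,
     26.3,
     7.0
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002,
      48.0
     ],
     [
      123.20000000000002,
      1.9599999999999997,
      0.5599999999999999
     ],
     [
      48.0,
      0.5599999999999999,
      4.0
     ]
    ]
   },
   "twin_pair": {
    "mean": [
     760.0,
     26.2,
     7.0,
     760.0,
     26.2,
     7.0
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002,
      48.0,
      17920.0,
      100.46655961064856,
      21.996363335788033
     ],
     [
      123.20000000000002,
      1.9599999999999997,
      0.5599999999999999,
      100.46655961064856,
      1.8619999999999994,
      0.2989581910568766
     ],
     [
      48.0,
      0.5599999999999999,
      4.0,
      21.996363335788033,
      0.2989581910568766,
      1.1999999999999997
     ],
     [
      17920.0,
      100.46655961064856,
      21.996363335788033,
      25600.0,
      123.20000000000002,
      48.0
     ],
     [
      100.46655961064856,
      1.8619999999999994,
      0.2989581910568766,
      123.20000000000002,
      1.9599999999999997,
      0.5599999999999999
     ],
     [
      21.996363335788033,
      0.2989581910568766,
      1.1999999999999997,
      48.0,
      0.5599999999999999,
      4.0
     ]
    ]
   }
  },
  "sex=1": {
   "singleton": {
    "mean": [
     860.0,
     26.4,
     6.8
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002,
      48.0
     ],
     [
      123.20000000000002,
      1.9599999999999997,
      0.5599999999999999
     ],
     [
      48.0,
      0.5599999999999999,
      4.0
     ]
    ]
   },
   "twin_pair": {
    "mean": [
     800.0,
     26.3,
     6.8,
     800.0,
     26.3,
     6.8
    ],
    "cov": [
     [
      25600.0,
      123.20000000000002,
      48.0,
      17920.0,
      100.46655961064856,
      21.996363335788033
     ],
     [
      123.20000000000002,
      1.9599999999999997,
      0.5599999999999999,
      100.46655961064856,
      1.8619999999999994,
      0.2989581910568766
     ],
     [
      48.0,
      0.5599999999999999,
      4.0,
      21.996363335788033,
      0.2989581910568766,
      1.1999999999999997
     ],
     [
      17920.0,
      100.46655961064856,
      21.996363335788033,
      25600.0,
      123.20000000000002,
      48.0
     ],
     [
      100.46655961064856,
      1.8619999999999994,
      0.2989581910568766,
      123.20000000000002,
      1.9599999999999997,
      0.5599999999999999
     ],
     [
      21.996363335788033,
      0.2989581910568766,
      1.1999999999999997,
      48.0,
      0.5599999999999999,
      4.0
     ]
    ]
   }
  }
 },
 "truncation": {
  "apgar": "apgar"
 }
}
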