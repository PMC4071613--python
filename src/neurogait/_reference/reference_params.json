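{
  "params": [
    0.026354712879602626,
    0.1902722198231204,
    0.20762342995541924,
    0.2159482127171906,
    0.21308515917968818,
    0.2794248090031783,
    0.10225972236946704,
    0.27815154579227963,
    0.5532713533301863,
    0.9684780248671737,
    0.5660613016847408,
    2.011278668853241,
    0.570611169018842,
    0.5640452885863008,
    1.5087395446997511,
    1.4740381827737554,
    1.492045867803294,
    1.0336994043716958,
    0.17015817245066833,
    0.5643252266931468,
    1.8445950815880439,
    0.1137901128544218,
    3.209750682318154,
    0.8355277087203362,
    4.020196217229659
  ],
  "score_stage": 0,
  "score_value": 2.093275737945842,
  "iteration": 30,
  "evaluations": 620,
  "seed": 1,
  "episode_duration_s": 6.0,
  "note": "desk-scale flat-ground search; see docs/methods.md"
}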