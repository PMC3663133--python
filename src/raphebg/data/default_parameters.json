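{
 "a1c": 2.333,
 "a1da": 0.167,
 "d1": 1,
 "a2c": 1.167,
 "a2da": 0.25,
 "d2": 1,
 "a3": 1.667,
 "a3md": 3.5,
 "a3mi": 2,
 "d3": 0.25,
 "a4th": 1.5,
 "d4": 1,
 "a5": 6.667,
 "a5sn": 0.01,
 "a5cx": 0.175,
 "d5": 1.5,
 "G": 0.72,
 "d6": 1,
 "a7": 1.2,
 "d7": 2,
 "a8": 58.833,
 "a8drn": 10,
 "d8": 10
}
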