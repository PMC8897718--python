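{
 "note": "Published reference parameters of the 4-10-1 extraction-yield network, read row-major as a 10x4 hidden-input matrix (rows = hidden neurons). The input-layer values carry an exact Nguyen-Widrow initialization signature (equal row norms, arithmetic bias ladder); see docs/methods.md.",
 "hidden_size": 10,
 "n_inputs": 4,
 "W1": {
  "shape": [
   10,
   4
  ],
  "order": "row-major",
  "values": [
   [
    0.343017,
    0.022306,
    -1.142627,
    2.184996
   ],
   [
    -0.14592,
    1.904915,
    1.374795,
    -0.81118
   ],
   [
    -0.97414,
    1.596739,
    -0.55674,
    1.545828
   ],
   [
    -0.52483,
    -1.50296,
    1.774247,
    -0.71819
   ],
   [
    0.070061,
    -2.20561,
    -0.84862,
    -0.77992
   ],
   [
    0.961495,
    1.638237,
    -0.48877,
    -1.53326
   ],
   [
    -0.93004,
    1.370738,
    -1.38043,
    1.24442
   ],
   [
    -1.55736,
    0.303836,
    1.3467,
    -1.3663
   ],
   [
    0.669556,
    1.987972,
    -0.72176,
    -1.12995
   ],
   [
    -0.266223,
    -0.5287,
    -1.04532,
    -2.18059
   ]
  ]
 },
 "b1": [
  -2.48959,
  1.936349,
  1.383106,
  0.829864,
  -0.27662,
  0.276621,
  -0.82986,
  -1.38311,
  1.936349,
  -2.48959
 ],
 "W2": [
  0.968797,
  -0.91973,
  -0.57294,
  -0.03547,
  -0.20334,
  -0.10741,
  -0.98684,
  0.321522,
  -0.31226,
  -0.60018
 ],
 "b2": 0.684928,
 "scaling": {
  "target_range": [
   -1.0,
   1.0
  ],
  "input_min": [
   200.0,
   50.0,
   15.0,
   20.0
  ],
  "input_max": [
   400.0,
   70.0,
   25.0,
   40.0
  ],
  "response_min": 6.83,
  "response_max": 7.5
 }
}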