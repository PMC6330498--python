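{
 "description": "Synthetic fixture found by Latin-hypercube screening of the simple implicit-motif oscillators: with substrate competition enabled the step response is a sustained oscillation; with classic per-target Michaelis-Menten denominators the same network and parameters settle to a stable fixed point.",
 "network": {
  "nodes": [
   {
    "id": "R",
    "role": "receptor-1"
   },
   {
    "id": "M",
    "role": "intermediate"
   },
   {
    "id": "O",
    "role": "output"
   }
  ],
  "links": [
   {
    "source": "O",
    "target": "R",
    "sign": -1
   },
   {
    "source": "R",
    "target": "M",
    "sign": -1
   },
   {
    "source": "R",
    "target": "O",
    "sign": 1
   }
  ],
  "implicit": [
   {
    "source": "M",
    "target": "O",
    "sign": -1,
    "mediator": "R"
   },
   {
    "source": "O",
    "target": "M",
    "sign": -1,
    "mediator": "R"
   }
  ],
  "figure_derived": true
 },
 "parameters": {
  "link": [
   [
    "O",
    "R",
    0.11822888845085784,
    0.031044051656995517
   ],
   [
    "R",
    "M",
    2.4047610496979637,
    0.0032073272426723157
   ],
   [
    "R",
    "O",
    6.916024666311017,
    0.07717234444443831
   ]
  ],
  "input": [
   [
    "R",
    0.13486024073190148,
    0.004091305496389476
   ]
  ],
  "basal": [
   [
    "M",
    "act",
    4.337197142598091,
    0.003486730412487839
   ],
   [
    "O",
    "deact",
    0.3977362453932355,
    0.003233804234857828
   ]
  ],
  "B": 0.5,
  "basal_input": 0.1,
  "stimulus_amplitude": 0.612833799195152
 }
}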