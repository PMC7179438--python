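{
  "score": 64.605,
  "features": [
    {"kind": "aromatic", "xyz": [-5.449, -10.056, 53.789], "radius": 1.1},
    {"kind": "aromatic", "xyz": [-4.468, -9.125, 52.185], "radius": 1.1},
    {"kind": "h_acceptor", "xyz": [-5.990, -10.020, 55.012], "radius": 0.5},
    {"kind": "h_acceptor", "xyz": [-4.278, -8.013, 52.455], "radius": 0.5},
    {"kind": "h_acceptor", "xyz": [-5.467, -11.213, 52.094], "radius": 0.5},
    {"kind": "h_acceptor", "xyz": [-5.735, -10.642, 47.065], "radius": 0.5}
  ]
}
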