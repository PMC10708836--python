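{
 "n_nodes": 5,
 "comment": "Part-level star graph: nodes 1..5 = LA, RA, LL, RL, TRUNK; each limb connected to the trunk node.",
 "edges": [
  [1, 5], [2, 5], [3, 5], [4, 5]
 ]
}
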