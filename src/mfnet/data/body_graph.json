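{
 "n_nodes": 20,
 "comment": "Natural-connectivity spanning tree over the 20-joint skeleton: each part center to its members, limb part centers (7, 4, 13, 10) and trunk members (2, 3, 16) to the trunk center 1. Joint numbers are 1-based.",
 "edges": [
  [7, 8], [7, 19], [7, 9],
  [4, 5], [4, 17], [4, 6],
  [13, 14], [13, 20], [13, 15],
  [10, 11], [10, 18], [10, 12],
  [1, 2], [1, 3], [1, 16],
  [1, 7], [1, 4], [1, 13], [1, 10]
 ]
}
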