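{
  "version": 1,
  "description": "Schematic letter waypoint plans, coordinates in micrometers, ~50 um extent.",
  "plans": {
    "A": [[0, 0], [15, 50], [30, 0], [22.5, 25], [7.5, 25]],
    "R": [[0, 0], [0, 50], [20, 50], [25, 40], [20, 30], [0, 30], [25, 0]],
    "S": [[25, 45], [10, 50], [0, 40], [10, 30], [20, 20], [10, 5], [0, 10]],
    "M": [[0, 0], [0, 50], [15, 25], [30, 50], [30, 0]],
    "U": [[0, 50], [0, 10], [7, 0], [23, 0], [30, 10], [30, 50]]
  }
}
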