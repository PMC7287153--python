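{
 "seed": 1,
 "q": 0.2730638922908559,
 "n_switches": 6,
 "node_states": {
  "nd0": "CS",
  "nd1": "CS",
  "nd2": "CS",
  "sp01": "CS",
  "nd3": "CS",
  "nd4": "CS",
  "sp02": "CS",
  "sp03": "CS",
  "nd5": "CS",
  "sp04": "CS",
  "sp05": "CS",
  "nd6": "CS",
  "sp06": "CS",
  "nd7": "CS",
  "nd8": "CS",
  "sp07": "CS",
  "sp08": "CS",
  "nd9": "CS",
  "sp09": "CS",
  "sp10": "CS",
  "nd10": "CS",
  "nd11": "WA",
  "nd12": "WA",
  "nd13": "WA",
  "nd14": "WA",
  "sp11": "WA",
  "nd15": "WA",
  "sp12": "WA",
  "sp13": "WA",
  "sp14": "CS",
  "nd16": "WA",
  "sp15": "WA",
  "sp16": "HF",
  "nd17": "WA",
  "nd18": "WA",
  "sp17": "WA",
  "nd19": "WA",
  "sp18": "WA",
  "sp19": "WA",
  "nd20": "WA",
  "nd21": "WA",
  "sp20": "WA",
  "sp21": "WA",
  "sp22": "HF",
  "nd22": "CS",
  "nd23": "CS",
  "sp23": "CS",
  "nd24": "CS",
  "nd25": "CS",
  "nd26": "CS",
  "sp24": "WA",
  "sp25": "CS",
  "nd27": "CS",
  "sp26": "CS",
  "sp27": "CS",
  "nd28": "CS",
  "nd29": "CS",
  "nd30": "CS",
  "sp28": "WA",
  "sp29": "CS",
  "sp30": "CS",
  "sp31": "CS",
  "nd31": "CS",
  "sp32": "CS",
  "nd32": "CS",
  "sp33": "CS",
  "sp34": "CS"
 },
 "clades": {
  "CladeI": [
   "sp01",
   "sp02",
   "sp03",
   "sp04",
   "sp05",
   "sp06",
   "sp07",
   "sp08",
   "sp09",
   "sp10"
  ],
  "CladeII": [
   "sp11",
   "sp12",
   "sp13",
   "sp14",
   "sp15",
   "sp16",
   "sp17",
   "sp18",
   "sp19",
   "sp20",
   "sp21",
   "sp22"
  ],
  "CladeIII": [
   "sp23",
   "sp24",
   "sp25",
   "sp26",
   "sp27",
   "sp28",
   "sp29",
   "sp30",
   "sp31",
   "sp32",
   "sp33",
   "sp34"
  ]
 },
 "lambda_per_trait": {
  "PH": 1.0,
  "LA": 1.0,
  "LMA": 1.0,
  "LT": 1.0,
  "LD": 1.0,
  "AR": 0.0,
  "RSR": 1.0
 },
 "habitat_effects": {
  "CS": {
   "LMA": 2.0,
   "LT": 2.0,
   "LD": 2.0,
   "RSR": 2.0
  }
 },
 "R": [
  [
   1.0,
   0.6,
   0.0,
   0.0,
   0.0,
   0.6,
   0.0
  ],
  [
   0.6,
   1.0,
   0.0,
   0.0,
   0.0,
   0.6,
   0.0
  ],
  [
   0.0,
   0.0,
   1.0,
   0.6,
   0.6,
   0.0,
   0.6
  ],
  [
   0.0,
   0.0,
   0.6,
   1.0,
   0.6,
   0.0,
   0.6
  ],
  [
   0.0,
   0.0,
   0.6,
   0.6,
   1.0,
   0.0,
   0.6
  ],
  [
   0.6,
   0.6,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.6,
   0.6,
   0.6,
   0.0,
   1.0
  ]
 ],
 "trait_names": [
  "PH",
  "LA",
  "LMA",
  "LT",
  "LD",
  "AR",
  "RSR"
 ]
}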