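{
 "linkages": [
  {
   "child": 1,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 0,
   "parent_carbon": 4
  },
  {
   "child": 2,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 1,
   "parent_carbon": 4
  },
  {
   "child": 3,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 2,
   "parent_carbon": 6
  },
  {
   "child": 4,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 3,
   "parent_carbon": 4
  },
  {
   "child": 5,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 4,
   "parent_carbon": 4
  },
  {
   "child": 6,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 5,
   "parent_carbon": 6
  },
  {
   "child": 7,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 6,
   "parent_carbon": 4
  },
  {
   "child": 8,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 7,
   "parent_carbon": 4
  },
  {
   "child": 9,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 8,
   "parent_carbon": 6
  },
  {
   "child": 10,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 9,
   "parent_carbon": 4
  },
  {
   "child": 11,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 10,
   "parent_carbon": 4
  },
  {
   "child": 12,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 11,
   "parent_carbon": 6
  },
  {
   "child": 13,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 12,
   "parent_carbon": 4
  },
  {
   "child": 14,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 13,
   "parent_carbon": 4
  },
  {
   "child": 15,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 14,
   "parent_carbon": 6
  },
  {
   "child": 16,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 15,
   "parent_carbon": 4
  },
  {
   "child": 17,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 16,
   "parent_carbon": 4
  },
  {
   "child": 18,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 17,
   "parent_carbon": 6
  },
  {
   "child": 19,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 18,
   "parent_carbon": 4
  }
 ],
 "name": "pullulan",
 "residues": [
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 0,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 1,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 2,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 3,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 4,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 5,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 6,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 7,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 8,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 9,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 10,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 11,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 12,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 13,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 14,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 15,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 16,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 17,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 18,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 19,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  }
 ],
 "root": 0
}
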