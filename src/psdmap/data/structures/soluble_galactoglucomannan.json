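{
 "linkages": [
  {
   "child": 1,
   "child_carbon": 1,
   "config": "beta",
   "parent": 0,
   "parent_carbon": 4
  },
  {
   "child": 2,
   "child_carbon": 1,
   "config": "beta",
   "parent": 1,
   "parent_carbon": 4
  },
  {
   "child": 3,
   "child_carbon": 1,
   "config": "beta",
   "parent": 2,
   "parent_carbon": 4
  },
  {
   "child": 4,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 3,
   "parent_carbon": 6
  },
  {
   "child": 5,
   "child_carbon": 1,
   "config": "beta",
   "parent": 3,
   "parent_carbon": 4
  },
  {
   "child": 6,
   "child_carbon": 1,
   "config": "beta",
   "parent": 5,
   "parent_carbon": 4
  },
  {
   "child": 7,
   "child_carbon": 1,
   "config": "beta",
   "parent": 6,
   "parent_carbon": 4
  },
  {
   "child": 8,
   "child_carbon": 1,
   "config": "alpha",
   "parent": 7,
   "parent_carbon": 6
  },
  {
   "child": 9,
   "child_carbon": 1,
   "config": "beta",
   "parent": 7,
   "parent_carbon": 4
  },
  {
   "child": 10,
   "child_carbon": 1,
   "config": "beta",
   "parent": 9,
   "parent_carbon": 4
  },
  {
   "child": 11,
   "child_carbon": 1,
   "config": "beta",
   "parent": 10,
   "parent_carbon": 4
  },
  {
   "child": 12,
   "child_carbon": 1,
   "config": "beta",
   "parent": 11,
   "parent_carbon": 4
  },
  {
   "child": 13,
   "child_carbon": 1,
   "config": "beta",
   "parent": 12,
   "parent_carbon": 4
  },
  {
   "child": 14,
   "child_carbon": 1,
   "config": "beta",
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
   "config": "beta",
   "parent": 15,
   "parent_carbon": 2
  },
  {
   "child": 17,
   "child_carbon": 1,
   "config": "beta",
   "parent": 14,
   "parent_carbon": 4
  },
  {
   "child": 18,
   "child_carbon": 1,
   "config": "beta",
   "parent": 17,
   "parent_carbon": 4
  },
  {
   "child": 19,
   "child_carbon": 1,
   "config": "beta",
   "parent": 18,
   "parent_carbon": 4
  },
  {
   "child": 20,
   "child_carbon": 1,
   "config": "beta",
   "parent": 19,
   "parent_carbon": 4
  },
  {
   "child": 21,
   "child_carbon": 1,
   "config": "beta",
   "parent": 20,
   "parent_carbon": 4
  },
  {
   "child": 22,
   "child_carbon": 1,
   "config": "beta",
   "parent": 21,
   "parent_carbon": 4
  },
  {
   "child": 23,
   "child_carbon": 1,
   "config": "beta",
   "parent": 22,
   "parent_carbon": 4
  }
 ],
 "name": "soluble_galactoglucomannan",
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
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 2,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 3,
   "modifications": [
    {
     "carbon": 3,
     "kind": "acetyl"
    }
   ],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": false,
   "id": 4,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Gal"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 5,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 6,
   "modifications": [
    {
     "carbon": 3,
     "kind": "acetyl"
    }
   ],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 7,
   "modifications": [
    {
     "carbon": 3,
     "kind": "acetyl"
    }
   ],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": false,
   "id": 8,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Gal"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 9,
   "modifications": [
    {
     "carbon": 2,
     "kind": "acetyl"
    }
   ],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 10,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 11,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 12,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Man"
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
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": false,
   "id": 15,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Gal"
  },
  {
   "anomeric_carbon": 1,
   "backbone": false,
   "id": 16,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Gal"
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
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 19,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 20,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 21,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 22,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Man"
  },
  {
   "anomeric_carbon": 1,
   "backbone": true,
   "id": 23,
   "modifications": [],
   "ring_carbons": 6,
   "sugar": "Glc"
  }
 ],
 "root": 0
}
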