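{
 "schema": "influence-topology/1",
 "species": [
  {
   "id": "x1",
   "clamped": false
  },
  {
   "id": "x2",
   "clamped": false
  },
  {
   "id": "x3",
   "clamped": false
  }
 ],
 "reactions": [
  {
   "id": "p1",
   "inputs": {
    "x3": "-r4"
   },
   "outputs": {
    "x1": 1
   }
  },
  {
   "id": "p2",
   "inputs": {
    "x1": "-r5"
   },
   "outputs": {
    "x2": 1
   }
  },
  {
   "id": "p3",
   "inputs": {
    "x2": "-r6"
   },
   "outputs": {
    "x3": 1
   }
  },
  {
   "id": "d1",
   "inputs": {
    "x1": "+r1"
   },
   "outputs": {
    "x1": -1
   }
  },
  {
   "id": "d2",
   "inputs": {
    "x2": "+r2"
   },
   "outputs": {
    "x2": -1
   }
  },
  {
   "id": "d3",
   "inputs": {
    "x3": "+r3"
   },
   "outputs": {
    "x3": -1
   }
  }
 ]
}
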