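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
   "id": "v1",
   "inputs": {
    "x1": "+r1"
   },
   "outputs": {
    "x1": -1,
    "x2": "+sigma1"
   }
  },
  {
   "id": "v2",
   "inputs": {
    "x3": "+r2"
   },
   "outputs": {
    "x1": "+sigma2",
    "x3": -1
   }
  },
  {
   "id": "v3",
   "inputs": {
    "x2": "+r3"
   },
   "outputs": {
    "x3": -1
   }
  },
  {
   "id": "v0",
   "inputs": {},
   "outputs": {
    "x1": -1,
    "x3": "+sigma3"
   }
  }
 ]
}
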