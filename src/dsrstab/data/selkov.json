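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
  }
 ],
 "reactions": [
  {
   "id": "v1",
   "inputs": {
    "x1": "+r0"
   },
   "outputs": {
    "x1": -1
   }
  },
  {
   "id": "v2",
   "inputs": {
    "x1": "+r1",
    "x2": "+r2"
   },
   "outputs": {
    "x1": "+sigma1",
    "x2": -1
   }
  },
  {
   "id": "v3",
   "inputs": {
    "x2": "+r3"
   },
   "outputs": {
    "x1": "+sigma2",
    "x2": -1
   }
  },
  {
   "id": "v0",
   "inputs": {},
   "outputs": {
    "x2": 1
   }
  }
 ]
}
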