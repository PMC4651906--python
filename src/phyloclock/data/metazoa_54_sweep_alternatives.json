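{
 "uncertain_E": [
  [
   "Hydra_magnipapillata",
   "Homo_sapiens"
  ],
  [
   "Trichoplax_adhaerens",
   "Hydra_magnipapillata"
  ]
 ]
}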