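{
 "table1_putative_mirnas.tsv": {
  "rows": 14,
  "sha256": "20422697bd33b858b70f7545f27ffa1cfd0f832be6913d60071fe1cf623cc9d6"
 },
 "table2_targets.tsv": {
  "rows": 169,
  "unique_genes": 152,
  "sha256": "8f24670c1dd8c7e1a6c04a0a879fb85aa8f5f4fe3e3eb4304e09d2bb886ecc4d"
 }
}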