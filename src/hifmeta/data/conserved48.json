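{
  "name": "conserved48",
  "description": "Consensus HIF target genes: bound by HIF and upregulated by hypoxia in all six cancer cell lines.",
  "genes": [
    "ADM", "AK4", "ALDOA", "ANGPTL4", "ANKRD37", "BHLHE40", "BNIP3L",
    "C4orf3", "C8orf58", "CTDSP1", "DDIT4", "DENND1A", "EGLN1", "ENO1",
    "ESYT2", "FUT11", "GBE1", "GPI", "HERC3", "HK2", "KCTD11", "KDM3A",
    "KDM4B", "KDM4C", "LDHA", "LONP1", "MIR210HG", "MXI1", "NCKIPSD",
    "NDRG1", "NPEPPS", "P4HA1", "PDLIM2", "PFKFB4", "PGAM1", "PGK1",
    "PKM", "PLOD2", "PNRC1", "RBPJ", "SAP30", "SCD", "SEMA4B",
    "SLC16A3", "SLC2A1", "STC2", "TNIP1", "ZNF395"
  ],
  "published_signatures": [
    "Benita", "Betts/Eustace", "Buffa", "Elvidge", "Ghazoui", "Halle",
    "Hu", "Ortiz-Barahoma", "Ragnum", "Seigneuric", "Sorensen",
    "Toustrup", "Winter", "Yang"
  ],
  "published_membership": {},
  "membership_note": "Per-gene membership flags for the 14 published hypoxia signatures could not be transcribed unambiguously from the available rendering of the source table; flags default to false pending verification against the formatted publication."
}
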