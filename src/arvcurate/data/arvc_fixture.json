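{
  "comment": "Packaged 26-gene ARVC curation fixture. Final tiers, point totals for DES/PLN/SCN5A, replication flags and overrides transcribe the published panel outcome; the genetic/experimental split for every other gene is a synthetic placeholder constrained to the published band and marked provisional pending gene-level subscores. clinvar_counts transcribe the published aggregate P/LP distribution (450/462 desmosomal; 1 CTNNA3 + 3 LMNA + 1 TGFB3 in limited-evidence genes); VUS/B/LB counts are synthetic filler for table realism.",
  "disease": "arrhythmogenic right ventricular cardiomyopathy",
  "genes": {
    "PKP2":   {"tier": "desmosomal", "genetic": "12",  "experimental": "6",   "replicated": true,  "override": "none"},
    "DSP":    {"tier": "desmosomal", "genetic": "12",  "experimental": "5",   "replicated": true,  "override": "none"},
    "DSG2":   {"tier": "desmosomal", "genetic": "11",  "experimental": "4.5", "replicated": true,  "override": "none"},
    "DSC2":   {"tier": "desmosomal", "genetic": "10",  "experimental": "3",   "replicated": true,  "override": "none"},
    "JUP":    {"tier": "desmosomal", "genetic": "10",  "experimental": "4",   "replicated": true,  "override": "none"},
    "TMEM43": {"tier": "other_definitive_moderate", "genetic": "11",  "experimental": "2",   "replicated": true,  "override": "none"},
    "DES":    {"tier": "other_definitive_moderate", "genetic": "7.5", "experimental": "2",   "replicated": false, "override": "none"},
    "PLN":    {"tier": "other_definitive_moderate", "genetic": "8.5", "experimental": "2.5", "replicated": false, "override": "none"},
    "SCN5A":  {"tier": "limited", "genetic": "4",   "experimental": "2",   "replicated": false, "override": "none"},
    "LMNA":   {"tier": "limited", "genetic": "4.5", "experimental": "0",   "replicated": false, "override": "none"},
    "CDH2":   {"tier": "limited", "genetic": "2.5", "experimental": "2",   "replicated": false, "override": "none"},
    "CTNNA3": {"tier": "limited", "genetic": "3",   "experimental": "0",   "replicated": false, "override": "none"},
    "TGFB3":  {"tier": "limited", "genetic": "2",   "experimental": "1.5", "replicated": false, "override": "none"},
    "TTN":    {"tier": "limited", "genetic": "2",   "experimental": "1",   "replicated": false, "override": "none"},
    "TJP1":   {"tier": "limited", "genetic": "2.5", "experimental": "0",   "replicated": false, "override": "none"},
    "MYH7":   {"tier": "limited", "genetic": "1.5", "experimental": "0",   "replicated": false, "override": "none"},
    "MYBPC3": {"tier": "limited", "genetic": "1",   "experimental": "0",   "replicated": false, "override": "none"},
    "MYL3":   {"tier": "limited", "genetic": "0.5", "experimental": "0",   "replicated": false, "override": "none"},
    "LDB3":   {"tier": "disputed_refuted", "genetic": "0.5", "experimental": "0",   "replicated": false, "override": "disputed"},
    "RYR2":   {"tier": "disputed_refuted", "genetic": "3.5", "experimental": "0.5", "replicated": false, "override": "refuted"},
    "ACTC1":  {"tier": "no_evidence", "genetic": "0", "experimental": "0", "replicated": false, "override": "none"},
    "MYL2":   {"tier": "no_evidence", "genetic": "0", "experimental": "0", "replicated": false, "override": "none"},
    "TNNC1":  {"tier": "no_evidence", "genetic": "0", "experimental": "0", "replicated": false, "override": "none"},
    "TNNI3":  {"tier": "no_evidence", "genetic": "0", "experimental": "0", "replicated": false, "override": "none"},
    "TNNT2":  {"tier": "no_evidence", "genetic": "0", "experimental": "0", "replicated": false, "override": "none"},
    "TPM1":   {"tier": "no_evidence", "genetic": "0", "experimental": "0", "replicated": false, "override": "none"}
  },
  "clinvar_counts": {
    "PKP2":   {"P": 150, "LP": 100, "VUS": 120, "B": 10, "LB": 30},
    "DSP":    {"P": 60,  "LP": 40,  "VUS": 150, "B": 8,  "LB": 25},
    "DSG2":   {"P": 35,  "LP": 25,  "VUS": 90,  "LB": 20},
    "DSC2":   {"P": 15,  "LP": 10,  "VUS": 60,  "LB": 15},
    "JUP":    {"P": 9,   "LP": 6,   "VUS": 40,  "LB": 10},
    "TMEM43": {"P": 2,   "LP": 1,   "VUS": 25,  "LB": 5},
    "PLN":    {"P": 3,   "LP": 1,   "VUS": 15,  "LB": 3},
    "DES":    {"VUS": 30, "LB": 6},
    "SCN5A":  {"VUS": 40, "LB": 10},
    "LMNA":   {"P": 2, "LP": 1, "VUS": 35, "LB": 8},
    "CDH2":   {"VUS": 12},
    "CTNNA3": {"LP": 1, "VUS": 20},
    "TGFB3":  {"LP": 1, "VUS": 10},
    "TTN":    {"VUS": 80, "LB": 20},
    "TJP1":   {"VUS": 8},
    "MYH7":   {"VUS": 30, "LB": 6},
    "MYBPC3": {"VUS": 25, "LB": 5},
    "MYL3":   {"VUS": 6},
    "LDB3":   {"VUS": 15, "LB": 4},
    "RYR2":   {"VUS": 120, "LB": 30},
    "ACTC1":  {"VUS": 5},
    "MYL2":   {"VUS": 4},
    "TNNC1":  {"VUS": 2},
    "TNNI3":  {"VUS": 6},
    "TNNT2":  {"VUS": 7},
    "TPM1":   {"VUS": 5}
  }
}
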