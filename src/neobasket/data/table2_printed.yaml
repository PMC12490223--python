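# Published efficacy table, transcribed for the recompute-vs-printed audit.
# Rate cells are "point (lower-upper)" in percent; survival cells are whole
# percent with an interval only where the estimate falls below 100%.
# ORR numerators/denominators are not derivable from the patient table
# (per-patient radiological best response is unpublished); the counts below
# are the ones implied by the printed percentages and set sizes.
orr_counts:
  colon:
    fas: {x: 11, n: 14}
    pps: {x: 9, n: 12}
  rectum:
    fas: {x: 7, n: 8}
    pps: {x: 5, n: 6}
printed:
  colon:
    fas:
      pcr: "57.1 (28.9-82.3)"
      orr: "78.6 (48.8-94.3)"
      r0: "85.7 (57.2-98.2)"
      trg0: "57.1 (28.9-82.3)"
      trg1: "14.3 (1.8-42.8)"
      trg2: "7.1 (0.2-33.9)"
      trg3: "7.1 (0.2-33.9)"
      efs_1yr: "100%"
      efs_2yr: "100%"
      os_1yr: "100%"
      os_2yr: "100%"
    pps:
      pcr: "66.7 (34.9-90.1)"
      orr: "75.0 (42.8-94.5)"
      r0: "100.0 (73.5-100.0)"
      trg0: "66.7 (34.9-90.1)"
      trg1: "16.7 (2.1-48.4)"
      trg2: "8.3 (0.2-38.5)"
      trg3: "8.3 (0.2-38.5)"
      dfs_1yr: "100%"
      dfs_2yr: "100%"
      efs_1yr: "100%"
      efs_2yr: "100%"
      os_1yr: "100%"
      os_2yr: "100%"
  rectum:
    fas:
      pcr: "75.0 (35.6-95.5)"
      orr: "87.5 (47.3-99.7)"
      r0: "75.0 (35.6-95.5)"
      trg0: "75.0 (35.6-95.5)"
      trg1: "0.0 (0.0-36.9)"
      trg2: "0.0 (0.0-36.9)"
      trg3: "0.0 (0.0-36.9)"
      efs_1yr: "88% (64%-100%)"
      efs_2yr: "88% (64%-100%)"
      os_1yr: "100%"
      os_2yr: "100%"
    pps:
      pcr: "100.0 (51.7-100.0)"
      orr: "83.3 (36.5-99.1)"
      r0: "100.0 (51.7-100.0)"
      trg0: "100.0 (51.7-100.0)"
      trg1: "0.0 (0.0-45.9)"
      trg2: "0.0 (0.0-45.9)"
      trg3: "0.0 (0.0-45.9)"
      dfs_1yr: "100%"
      dfs_2yr: "100%"
      efs_1yr: "100%"
      efs_2yr: "100%"
      os_1yr: "100%"
      os_2yr: "100%"
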