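# 14-run sensitivity design: two catch-series start years (1971 reconstructed,
# 1992 nominal) crossed with no index / six abundance indices. Column names
# follow the CMSY configuration convention. Note the narrower r.hi for runs
# 12-14, carried as configured.
runs:
  - {run: 1,  label: BSH_ATS,            start.yr: 1971, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 1995, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: "None", force.cmsy: true,  process.error: 0.05}
  - {run: 2,  label: BSH_ATS_CPUE_UR,    start.yr: 1971, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 1995, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: UR}
  - {run: 3,  label: BSH_ATS_CPUE_BR,    start.yr: 1971, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 1995, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: BR}
  - {run: 4,  label: BSH_ATS_CPUE_JP,    start.yr: 1971, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 1995, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: JP}
  - {run: 5,  label: BSH_ATS_CPUE_ESP,   start.yr: 1971, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 1995, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: ESP}
  - {run: 6,  label: BSH_ATS_CPUE_CHTP,  start.yr: 1971, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 1995, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: CHTP}
  - {run: 7,  label: BSH_ATS_JCPUE,      start.yr: 1971, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 1995, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: JCPUE}
  - {run: 8,  label: BSH_ATS_n,          start.yr: 1992, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 2011, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: "None", force.cmsy: true,  process.error: 0.05}
  - {run: 9,  label: BSH_ATS_n_CPUE_UR,  start.yr: 1992, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 2011, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: UR}
  - {run: 10, label: BSH_ATS_n_CPUE_BR,  start.yr: 1992, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 2011, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: BR}
  - {run: 11, label: BSH_ATS_n_CPUE_JP,  start.yr: 1992, end.yr: 2020, r.low: 0.045, r.hi: 0.3, stb.low: 0.4, stb.hi: 0.8, intb.yr: 2011, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: JP}
  - {run: 12, label: BSH_ATS_n_CPUE_ESP, start.yr: 1992, end.yr: 2020, r.low: 0.045, r.hi: 0.1, stb.low: 0.4, stb.hi: 0.8, intb.yr: 2011, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: ESP}
  - {run: 13, label: BSH_ATS_n_CPUE_CHTP, start.yr: 1992, end.yr: 2020, r.low: 0.045, r.hi: 0.1, stb.low: 0.4, stb.hi: 0.8, intb.yr: 2011, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,  force.cmsy: false, process.error: 0.05, index: CHTP}
  - {run: 14, label: BSH_ATS_n_JCPUE,    start.yr: 1992, end.yr: 2020, r.low: 0.045, r.hi: 0.1, stb.low: 0.4, stb.hi: 0.8, intb.yr: 2011, intb.low: 0.2, intb.hi: 0.9, endb.low: 0.1, endb.hi: 0.7, btype: CPUE,   force.cmsy: false, process.error: 0.05, index: JCPUE}
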