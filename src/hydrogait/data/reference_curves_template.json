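{
  "_comment": "Template for comparative cost-of-transport curves. Fill 'coefficients' with polynomial coefficients (highest power first) of COT(speed) in J/kg/m with speed in m/s, and 'speed_range' with the validity range of the source equation. Entries left null are skipped by the loader.",
  "swimming_crawl": {"coefficients": null, "speed_range": [0.96, 1.8]},
  "dryland_walking": {"coefficients": null, "speed_range": [0.3, 2.0]},
  "hypogravity_surface": {"coefficients": null, "speed_range": [0.2, 0.8]}
}
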