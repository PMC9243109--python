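# one 3-day incubation of the full trispecific blood model
preset: trispecific
experiment:
  dose_nM: 0.672
  duration_h: 72.0
  label: high-dose-audit
flux_tolerance: 1.0e-6
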