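# bispecific-vs-trispecific dose-response study on the CD8-only
# blood-composition model (desk-scale)
preset: reduced-blood
doses: [1.0e-5, 1.0e-4, 1.0e-3, 1.0e-2, 0.1, 1.0, 10.0]
duration_h: 72.0
population_size: 1
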