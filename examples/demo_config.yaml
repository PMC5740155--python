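# Demo: full pipeline on a small synthetic genome (runs in ~1 minute).
#   foundersweep run-all --config examples/demo_config.yaml --out demo_out
N1: 35000
N2b: 14.4
N2f: 1290
T: 50
mu: 1.0e-8
chrom_lengths:
  chr1: 300000
sweeps:
  - chrom: chr1
    center: 150000
null_reps: 2000
fit_coarse: 9
seed: 1
stages: [simulate, filter, stats, fit, calibrate, scan, clr]
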