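seed = 0
outdir = "results"

[generator]
n_times = 240
ts_min = 12.0
noise_sigma = 0.02
replicates = 3
iptg_doses_mm = [0.01, 0.1, 0.3, 0.6, 1.0, 10.0]
arabinose_pct = 0.01
x0 = 0.05
xmax = 1.2
mu = 0.01
lag_min = 60.0

[identification]
order = 2

[analysis]
od_threshold = 0.6
od_floor = 0.05
alpha = 0.05
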