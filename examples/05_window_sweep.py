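"""The window-configuration sweep: which segmentation wins?

Runs the full pipeline on a 100 fall / 100 ADL synthetic dataset at the
hardest difficulty (fall and ADL impact amplitudes overlap, so the class
signal lives in the pre- and post-impact intervals), sweeps a reduced
(t_max = 2 s) window grid with the 5-fold cross-validated SVM and prints the
maximal Fscore per window class plus a pairwise-maximum grid over (t3, t4).
Multi-window configurations should match or beat the single impact window.
"""

import fallseg as fs

cfg = fs.GeneratorConfig(
    sampling_rate_hz=50.0, n_fall_records=100, n_adl_records=100, seed=11
)
records, _ = fs.generate_dataset(cfg)
prepared = fs.prepare_event_centered(records)
print(
    f"{len(records)} records -> {len(prepared.ecrs)} event-centered records "
    f"at threshold {prepared.threshold_g} g"
)

configs = fs.enumerate_configs(t_max=2.0)
sweep = fs.run_sweep(prepared.ecrs, configs, seed=11)

best = fs.best_by_class(sweep)
best["fscore_pct"] = (100 * best["fscore"]).round(1)
print("\nmax Fscore per window class (and the achieving t1..t4):")
print(best[["window_class", "fscore_pct", "t1", "t2", "t3", "t4"]].to_string(index=False))

print("\nmax Fscore over configurations sharing each (t3, t4) — the W1 extent:")
print((100 * fs.pairwise_max_grid(sweep, ("t3", "t4"))).round(1).to_string())
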