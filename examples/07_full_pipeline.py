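"""One-command synthetic session through the whole pipeline.

Generates a tone-driven critical-cascade session (9 frequencies x 3 sound
levels), thresholds it, extracts and classifies ensembles, fits the
avalanche statistics with their shuffle null, and summarizes evoked
activity by sound level.  Equivalent CLI:

    avakit run-all --config examples/pipeline_demo.yaml --out scratch/demo
"""

from avakit.pipeline import run_pipeline

config = {
    "seed": 7,
    "synthetic": {
        "n_neurons": 80,
        "protocol": {"reps": 2, "isi_range": [2.0, 3.0]},
    },
    "output_dir": "scratch/pipeline_demo",
}

report = run_pipeline(config)
fits = report["stages"]["fit"]
print("ensembles:", report["stages"]["avalanches"]["n_ensembles"],
      f"({report['stages']['avalanches']['n_evoked']} evoked)")
for key in ("ongoing_size", "evoked_size", "shuffled_size"):
    b = fits[key]
    print(f"{key:>14}: n={b['n']:5d}  LLR {b['llr']:+9.1f}  "
          f"slope {b['alpha_ks']:+.2f}")
print("level trend (Spearman rho, size vs dB):", round(fits["level_trend"]["rho_size"], 2))
# Ongoing and evoked LLR are positive (avalanche statistics in both
# regimes), the shuffled control is negative, and mean evoked ensemble
# size increases with sound level.
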