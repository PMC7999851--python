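"""Control precision and reference-limit derivation.

Simulates repeatability (one donor, six repeats) and reproducibility
(nine donors) series for the three control levels, summarises them as
mean / SD / %CV, and derives PRP validity limits from a 25-batch
healthy-donor series.
"""

import numpy as np

from hitfca import (
    RunConfig, SimConfig, analyze_simulated, batch_stats, cv_acceptability,
    derive_reference_limits, qualify_control, simulate_control_series,
)

cfg = SimConfig(seed=3)
runcfg = RunConfig(spillover=cfg.spillover)

print("level  mode            n  mean   sd    %cv   cv-gate  all qualified")
for level in ("QCH", "QCM", "QCB"):
    for mode, n in (("repeatability", 6), ("reproducibility", 9)):
        runs = simulate_control_series(level, n, cfg, seed=42, mode=mode)
        heplas = [analyze_simulated(r, runcfg)["result"]["hepla"] for r in runs]
        s = batch_stats(heplas).rounded()
        ok = all(qualify_control(h, level) for h in heplas)
        print(f"{level}  {mode:15s} {s.n}  {s.mean:5.1f} {s.sd:5.1f} {s.cv:6.1f}"
              f"  {cv_acceptability(s, level):7s}  {ok}")

rng = np.random.default_rng(0)
limits, warnings = derive_reference_limits(rng.normal(11.1, 4.1, 25), rng.normal(92.0, 3.55, 25))
print()
print("PRP validity limits from 25 healthy-donor batches (mean +/- 2 SD):")
print({k: round(v, 1) for k, v in limits.items()})
print("A PRP is usable when %NEG falls inside [neg_low, neg_high] and")
print("%POS is at least pos_low.")
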