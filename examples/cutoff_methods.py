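"""Compare the intersection cutoff with the legacy mean + 2 SD cutoff.

Both thresholds are computed from the same simulated NEG/POS control
tubes; the POS tube is then classified under each. The legacy rule
assumes the NEG log-FL1 distribution is a single Gaussian; healthy
donor platelets are in fact partly pre-activated (~11% here), which
inflates the NEG mean + 2 SD and pushes the legacy threshold into the
activated mode — the intersection rule is immune to this.
"""

from hitfca import (
    RunConfig, SamplePhenotype, SimConfig, simulate_run,
    apply_compensation, to_log, gate_platelet_scatter, gate_cd41_positive,
    paired_densities, intersection_cutoff, legacy_cutoff, percent_activation,
)

cfg = SimConfig(seed=4)
sim = simulate_run(cfg, SamplePhenotype(kind="non_hit"), seed=4)

prepared = {}
for role in ("NEG", "POS"):
    t = to_log(apply_compensation(sim.tables[role], cfg.spillover))
    gate = gate_cd41_positive(t, gate_platelet_scatter(t))
    prepared[role] = (t, gate)

neg_curve, pos_curve = paired_densities(*prepared["NEG"], *prepared["POS"])
inter = intersection_cutoff(neg_curve, pos_curve)
legacy = legacy_cutoff(*prepared["NEG"])

print(f"intersection cutoff: log-FL1 = {inter.value:.3f}")
print(f"legacy mean+2SD    : log-FL1 = {legacy.value:.3f}")
for cut in (inter, legacy):
    pos_pct = percent_activation(*prepared["POS"], cut).percent_activated
    neg_pct = percent_activation(*prepared["NEG"], cut).percent_activated
    print(f"  {cut.method:15s} -> %POS = {pos_pct:5.1f}, %NEG = {neg_pct:4.1f}")
print()
print("The partly pre-activated NEG tube violates the legacy rule's")
print("normality assumption: its inflated mean+2SD threshold cuts into the")
print("activated mode and understates %POS. The intersection rule places")
print("the threshold where the resting and activated densities cross.")
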