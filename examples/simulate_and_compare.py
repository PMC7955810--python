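"""Differential HDX-MS on a synthetic two-state experiment.

Builds a 400-residue protein with random per-residue protection factors,
simulates EX2 deuterium uptake for a reference state and a state with a
10-fold protection drop over residues 175–189 (the kind of localized
destabilisation an activating point mutation produces), then runs the
three-criterion significance filter and the summed #D-difference profile.
"""

import numpy as np

from hdxdyn.differential import (
    compare_states,
    coverage_stats,
    peptide_significance,
    summed_differences,
    summed_to_frame,
)
from hdxdyn.synth import (
    ExchangeModel,
    PerturbationSpec,
    SimulationConfig,
    generate_peptide_map,
    simulate_uptake,
)

rng = np.random.default_rng(0)
sequence = "".join(rng.choice(list("ACDEFGHIKLMNQRSTVWY"), 400))

model = ExchangeModel.random(sequence, seed=7)          # PF ~ log-uniform [10, 1e6]
config = SimulationConfig(seed=11)                      # 3/30/300/3000 s, n=3, 0.05 Da noise
peptides = generate_peptide_map(sequence, config)
cov = coverage_stats(peptides, sequence)
print(f"peptide map: {cov['n_peptides']} peptides, "
      f"{cov['pct_exchangeable_covered']:.1f}% of exchangeable amides covered")

region = PerturbationSpec(175, 189, pf_multiplier=0.1)  # 10x less protected
dataset = simulate_uptake(model, peptides, config, perturbations=[region])

comparison = compare_states(
    dataset.subset_state("reference"), dataset.subset_state("perturbed")
)
flags = {p.key(): peptide_significance(comparison.for_peptide(p)) for p in peptides}
significant = [p for p in peptides if flags[p.key()] != "none"]
print(f"significant peptides (>5%, >0.4 Da, p<0.01 at any timepoint): {len(significant)}")
for p in significant:
    print(f"  {p.start}-{p.end}  {flags[p.key()]}")

profile = summed_to_frame(summed_differences(comparison))
top = profile.iloc[profile["sum_delta_d"].abs().idxmax()]
print(f"largest summed #D difference: {top.sum_delta_d:+.2f} ± {top.sd_sum:.2f} Da "
      f"at central residue {top.central_residue:.1f}")
# Peptides overlapping 175-189 light up; everything else stays at noise level.
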