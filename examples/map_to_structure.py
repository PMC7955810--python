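"""Color a structure by HDX differences via the B-factor column.

Re-runs the two-state comparison from simulate_and_compare.py, resolves the
significant peptides to per-residue %-difference values, and writes them
into the B-factor field of a (here: synthetic) PDB so a molecular viewer
can color the structure by exchange change.  Residues without coverage get
the -1.00 "no data" sentinel.
"""

import tempfile
from pathlib import Path

import numpy as np

from hdxdyn.differential import compare_states
from hdxdyn.structmap import read_bfactors, residues_from_peptides, write_bfactor_pdb
from hdxdyn.synth import (
    ExchangeModel,
    PerturbationSpec,
    SimulationConfig,
    generate_peptide_map,
    make_toy_ensemble,
    simulate_uptake,
)

rng = np.random.default_rng(0)
sequence = "".join(rng.choice(list("ACDEFGHIKLMNQRSTVWY"), 400))
model = ExchangeModel.random(sequence, seed=7)
config = SimulationConfig(seed=11)
peptides = generate_peptide_map(sequence, config)
dataset = simulate_uptake(model, peptides, config,
                          perturbations=[PerturbationSpec(175, 189, 0.1)])
comparison = compare_states(dataset.subset_state("reference"),
                            dataset.subset_state("perturbed"))

value_map = residues_from_peptides(comparison, rule="max-abs")
print(f"residues with a mapped %-difference: {len(value_map.residues())} "
      f"({value_map.residues()[0]}..{value_map.residues()[-1]})")

workdir = Path(tempfile.mkdtemp())
# stand-in structure: a synthetic Cα trace written as a PDB (author numbering
# 1..400 to match the synthetic protein)
structure = make_toy_ensemble("harmonic", n_frames=1, n_atoms=400, sd=0.0, seed=1)
pdb_in = workdir / "synthetic_structure.pdb"
structure.to_pdb(pdb_in, chain="A")

pdb_out = workdir / "colored.pdb"
report = write_bfactor_pdb(pdb_in, pdb_out, value_map, chain="A",
                           legend_path=workdir / "legend.json")
print(f"wrote {report.n_atoms_written} atoms; "
      f"{report.n_residues_matched} mapped residues matched the chain")

back = read_bfactors(pdb_out, "A")
example = value_map.residues()[0]
print(f"residue {example}: map value {value_map[example].value:+.2f}% "
      f"({value_map[example].category}), B-factor read-back {back[example]:+.2f}")
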