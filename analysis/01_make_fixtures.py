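#!/usr/bin/env python
"""Materialize one synthetic workspace: a 3x3 pseudo-tubulin patch with a
docked domain (PDB), its crosslink table (CSV), the domain density map (MRC),
and a mixed-state MS1 envelope (CSV).

Text tables go to results/fixtures; the binary density map goes to scratch/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from dcxlattice.cli import write_pdb_from_inputs
from dcxlattice.pipeline import StageSpec, build_stage_inputs
from dcxlattice.synthetic_data import simulate_density, simulate_ms1

SEED = 0
OUT = Path("results/fixtures")
SCRATCH = Path("scratch")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    inputs = build_stage_inputs(StageSpec(stage=1, restraint_subset="xl_plus_em"),
                                seed=SEED)
    write_pdb_from_inputs(inputs, OUT / "lattice_with_domain.pdb")
    inputs.xls.to_csv(OUT / "crosslinks.csv")
    beads = [inputs.topology.all_beads[i] for i in inputs.mobile_selection]
    dm = simulate_density(np.array([b.center for b in beads]),
                          np.array([b.radius for b in beads]),
                          np.array([b.mass for b in beads]), seed=SEED)
    dm.write_mrc(SCRATCH / "domain_density.mrc")
    obs, _ = simulate_ms1("mixed", noise_sd=0.02, seed=SEED)
    pd.DataFrame({"mz": obs.mz, "intensity": obs.intensity}).to_csv(
        OUT / "ms1_mixed.csv", index=False)
    print(f"wrote {OUT}/lattice_with_domain.pdb ({len(inputs.topology.fine_beads)} residues),")
    print(f"      {OUT}/crosslinks.csv ({len(inputs.xls)} links),")
    print(f"      {SCRATCH}/domain_density.mrc (grid {dm.data.shape}),")
    print(f"      {OUT}/ms1_mixed.csv ({len(obs.mz)} peaks)")


if __name__ == "__main__":
    main()
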