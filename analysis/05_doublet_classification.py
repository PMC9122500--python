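#!/usr/bin/env python
"""Classify 14N/15N crosslink MS1 doublets: the inner:outer intensity ratio
separates intra-protein, inter-protein, and mixed crosslink populations.

Simulates the three archetypes noiselessly and then 50 noisy replicates of the
mixed state, reporting the call rates.
"""
from pathlib import Path

import pandas as pd

from dcxlattice.isotope_doublet import classify_doublet
from dcxlattice.synthetic_data import simulate_ms1

SEED = 3


def main() -> None:
    rows = []
    for cls in ("intra", "inter", "mixed"):
        obs, cands = simulate_ms1(cls)
        call = classify_doublet(obs, cands)
        rows.append({"truth": cls, "noise_sd": 0.0, "call": call.label,
                     "inner_outer_ratio": call.inner_outer_ratio})
        print(f"noiseless {cls:5s} -> {call.label:5s} "
              f"(inner:outer = {call.inner_outer_ratio:.3f})")
    hits = 0
    _, cands = simulate_ms1("mixed")
    for k in range(50):
        obs, _ = simulate_ms1("mixed", noise_sd=0.02, seed=SEED + k)
        call = classify_doublet(obs, cands)
        hits += call.label == "mixed"
        rows.append({"truth": "mixed", "noise_sd": 0.02, "call": call.label,
                     "inner_outer_ratio": call.inner_outer_ratio})
    print(f"mixed state at 2% noise: {hits}/50 replicates called mixed")
    Path("results").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv("results/doublet_calls.csv", index=False)
    print("table -> results/doublet_calls.csv")


if __name__ == "__main__":
    main()
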