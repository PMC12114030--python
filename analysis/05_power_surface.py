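#!/usr/bin/env python
"""Power surface of the exact rank-sum test under extreme imbalance.

Simulates N(0,1) controls versus N(beta,1) knockouts with 258 controls
over beta in 0.5..5 and knockout group sizes 1..10 at the study-wise
threshold 9e-7, 10,000 trials per cell, and writes the table and heatmap.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from komet.power import PowerGridSpec, power_report, simulate_power

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    spec = PowerGridSpec(threshold=9e-7, n_trials=10_000, seed=1)
    grid = simulate_power(spec)
    power_report(grid, tsv_path=BASE / "power.tsv", png_path=BASE / "power.png")
    print(f"knockout sizes {grid.unattainable} cannot reject at threshold "
          f"{spec.threshold:g} (smallest attainable p too large)")
    print(grid.power.round(3).to_string())
    print(f"power at beta=3, 5 knockouts: {grid.power.loc[3.0, 5]:.4f} "
          f"(>=0.80 within Monte-Carlo error)")


if __name__ == "__main__":
    main()
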