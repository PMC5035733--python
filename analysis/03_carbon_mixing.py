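"""Quantify substrate-derived carbon in CO2 and microbial biomass pools.

Simulates delta-13C measurement series (3 replicates, 0.5 per-mil noise)
for amended and control microcosms, applies the two-pool mixing model with
control-derived reference signatures, and compares recovered percentages
with the simulated ground truth. Also prints the amendment bookkeeping:
mg C per microcosm, ug C per g soil, and the amendment's share of soil
organic carbon. Tables go to results/mixing/.
"""

from pathlib import Path

import pandas as pd

from rrnasip import amendment_per_gram, default_config, io
from rrnasip.mixing import mixing_table, summarize_mixing
from rrnasip.pipeline import IsotopeScenario
from rrnasip.simulate import simulate_isotope_series

import numpy as np

OUT = Path(__file__).resolve().parent.parent / "results" / "mixing"
SEED = 1
SOIL_ORGANIC_C_UG_PER_G = 13_700.0  # 1.37 % organic C


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    per_g = amendment_per_gram(12.0, 50.0)
    print(f"amendment: 12.0 mg C per 50 g soil = {per_g:.0f} ug C/g soil "
          f"({per_g / SOIL_ORGANIC_C_UG_PER_G * 100:.3f}% of soil organic C)")

    config = default_config(seed=SEED)
    scen = IsotopeScenario()
    frames = []
    for i, substrate in enumerate(config.substrates):
        rng = np.random.default_rng([SEED, i])
        frames.append(
            simulate_isotope_series(
                config, scen.true_fractions, scen.delta_reference,
                scen.delta_substrate, scen.delta_soil,
                substrate=substrate, rng=rng,
            )
        )
    rng = np.random.default_rng([SEED, 99])
    frames.append(
        simulate_isotope_series(
            config, {k: 0.0 for k in scen.true_fractions}, scen.delta_reference,
            scen.delta_substrate, scen.delta_soil, substrate="control", rng=rng,
        )
    )
    measurements = pd.concat(frames, ignore_index=True)
    io.write_measurements_csv(measurements, OUT / "delta13c_measurements.csv")

    per_rep = mixing_table(
        measurements,
        {s: scen.delta_substrate for s in config.substrates},
        scen.delta_soil,
    )
    per_rep.to_csv(OUT / "substrate_derived_c.csv", index=False)
    summary = summarize_mixing(per_rep)
    summary["truth"] = [
        100 * scen.true_fractions[(row.pool, row.timepoint)] for row in summary.itertuples()
    ]
    summary.to_csv(OUT / "substrate_derived_c_summary.csv", index=False)
    print("\npercent substrate-derived C (mean of 3 replicates vs truth):\n")
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.2f}"))


if __name__ == "__main__":
    main()
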