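#!/usr/bin/env python
"""Monte-Carlo validation of the spectrometry chain on synthetic data.

Draws Poisson gamma-counting replicates at a fixed true ²³⁸U activity
(8.96 Bq/kg, the survey's SS1 value) under the default counting model
(36000 s live time, 1 kg sample), recovers the activity through the
series-averaging quantification, and reports bias, uncertainty
calibration and 3σ coverage over 1000 replicates.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from terradose import series_activity
from terradose.io import ActivityRecord
from terradose.spectrometry import default_line_registry
from terradose.synthetic import generate_counting_data, stage_rng

OUT = Path(__file__).resolve().parents[1] / "results"
TRUTH = 8.96  # Bq/kg


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2024)
    parser.add_argument("--replicates", type=int, default=1000)
    args = parser.parse_args()

    OUT.mkdir(exist_ok=True)
    rec = ActivityRecord("truth", TRUTH, 0.0, 0.0)
    lines = [l for l in default_line_registry() if l.series == "U-238"]
    rng = stage_rng(args.seed, "counting")

    recovered, sigmas = [], []
    for _ in range(args.replicates):
        a, s = series_activity(generate_counting_data(rec, lines, rng=rng))
        recovered.append(a)
        sigmas.append(s)
    recovered = np.asarray(recovered)
    sigmas = np.asarray(sigmas)
    coverage = float(np.mean(np.abs(recovered - TRUTH) <= 3 * sigmas))

    report = pd.DataFrame(
        {
            "quantity": ["true_activity_bq_kg", "mean_recovered", "bias_pct",
                         "empirical_sd", "mean_reported_sd", "coverage_3sigma"],
            "value": [TRUTH, recovered.mean(),
                      100 * (recovered.mean() / TRUTH - 1),
                      recovered.std(ddof=1), sigmas.mean(), coverage],
        }
    )
    report.to_csv(OUT / "synthetic_recovery.csv", index=False)
    print(report.to_string(index=False))
    print(f"\n{args.replicates} replicates: recovered "
          f"{recovered.mean():.3f} Bq/kg (truth {TRUTH}), "
          f"3-sigma coverage {coverage:.1%}")


if __name__ == "__main__":
    main()
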