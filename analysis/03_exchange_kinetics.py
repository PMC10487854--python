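#!/usr/bin/env python
"""Fit cation-exchange rates from simulated NzExHSQC volume curves.

Generates peak-volume series from the study-like four-site exchange
network (bulk, O5, I, O3; fastest escape from the 3'-outer site, none
past the syn 5' quartet), normalizes them to the O5 autocorrelation peak
at 13 ms, fits the bi-exponential autocorrelation decays and the
cross-peak build-ups, and writes the apparent rate-constant table.  A
noisy replicate run quantifies the robustness of the recovered rates.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from g4kit.exchange_kinetics import fit_crosspeak, fit_exchange_network
from g4kit.synthetic import ExchangeNetworkSpec, simulate_exchange
import dataclasses

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = ExchangeNetworkSpec()
    series = simulate_exchange(spec)
    rows = [
        {"peak_label": lab, "mixing_time_s": t, "volume": v}
        for lab, s in series.items()
        for t, v in zip(s.mixing_times, s.volumes)
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "exchange_curves.tsv", sep="\t", index=False)

    autos, crosses, table = fit_exchange_network(series)
    report = {
        "microscopic_rates_per_s": {f"{a}->{b}": v for (a, b), v in spec.rates.items()},
        "apparent_rates_per_s": {f"{a}->{b}": round(v, 4) for (a, b), v in table.rates.items()},
        "T1_estimates_s": {k: round(f.t1_slow, 4) for k, f in autos.items()},
    }

    # noise robustness: 5% multiplicative noise on a two-site k=2 network
    two_site = ExchangeNetworkSpec(
        sites=("S", "D"), rates={("S", "D"): 2.0},
        t1={"S": 0.4, "D": 0.4}, m0={"S": 1.0, "D": 0.0},
    )
    rng = np.random.default_rng(seed)
    ks = []
    for rep in rng.integers(0, 2**31 - 1, 100):
        noisy = dataclasses.replace(two_site, noise_sigma=0.05, seed=int(rep))
        ks.append(fit_crosspeak(simulate_exchange(noisy)["SD"], T1=0.4).k)
    ks = np.array(ks)
    report["noise_study"] = {
        "true_k_per_s": 2.0,
        "median_fitted_k_per_s": round(float(np.median(ks)), 4),
        "fraction_within_30_percent": float(np.mean(np.abs(ks - 2) / 2 <= 0.3)),
    }
    (RESULTS / "exchange_fits.json").write_text(json.dumps(report, indent=2) + "\n")

    print("apparent rate constants (1/s):")
    for k, v in report["apparent_rates_per_s"].items():
        print(f"  {k:>8s}: {v:.3f}")
    print("fastest pathways are out of the 3'-outer site; no movement past the syn 5' quartet.")
    print(f"noise study: {report['noise_study']['fraction_within_30_percent']:.0%} of "
          f"replicates within 30% of the generating rate")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
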