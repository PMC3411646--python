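#!/usr/bin/env python
"""Parameter-recovery and calibration checks against planted truth:
polarization polarity/branch recovery, indel size-spectrum goodness of
fit, SSR threshold-set nesting and slippage attribution, relative-rate
type-I error, and the Ks-clock identities. Writes results/recovery.json."""

import argparse
import json
from pathlib import Path

from plastdiverge.experiments import (dating_identity_experiment,
                                      polarization_and_spectrum_recovery,
                                      ssr_attribution_experiment,
                                      synonymous_process_experiment,
                                      tajima_type1_experiment,
                                      threshold_subset_experiment)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/recovery.json")
    args = ap.parse_args()

    report = {
        "polarization_and_spectrum":
            polarization_and_spectrum_recovery(args.seed),
        "ssr_attribution": ssr_attribution_experiment(args.seed),
        "ssr_threshold_nesting": threshold_subset_experiment(args.seed),
        "tajima_type1": tajima_type1_experiment(args.seed),
        "dating_identity": dating_identity_experiment(args.seed),
        "synonymous_process": synonymous_process_experiment(args.seed),
    }
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2, default=float))

    p = report["polarization_and_spectrum"]
    print(f"polarization: {p['n_recovered']}/{p['n_planted']} planted indels "
          f"recovered with correct polarity and branch "
          f"({100 * p['recovery_fraction']:.1f}%)")
    print(f"size spectrum: chi2 GOF p = {p['spectrum_gof_p']:.3f} "
          f"over {p['n_spectrum_events']} loci")
    s = report["ssr_attribution"]
    print(f"slippage-only indels attributed to SSRs: "
          f"{100 * s['attributed_fraction']:.1f}% of {s['n_short_indels']}")
    t = report["tajima_type1"]
    print(f"relative-rate type-I error: {100 * t['rejection_rate']:.2f}% "
          f"(nominal 5%)")
    d = report["dating_identity"]
    print(f"Ks-clock: A vs D dates to {d['t_a_vs_d_my']:.2f} MY at "
          f"rs = {d['rs_per_year']:.3e}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
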