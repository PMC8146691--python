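#!/usr/bin/env python
"""Mechanism recovery: does entropy of the local-skewness map (s_e) track
spatial heterogeneity of asymmetry?

Pairs phantoms that differ only in skew-shape spread (6 vs 0, same seed)
and counts how often the heterogeneous twin scores the higher s_e; also
reports the fixed benchmark arithmetic of the selection/ROC machinery.
Writes results/mechanism.json.
"""

import json
from pathlib import Path

from localrad import (
    bonferroni_threshold,
    count_included,
    extract_features,
    youden_cutoff,
)
from localrad.synthetic import PhantomSpec, generate_phantom

ROOT = Path(__file__).resolve().parents[1]
N_PAIRS = 20


def main() -> None:
    wins = 0
    deltas = []
    for seed in range(N_PAIRS):
        het = extract_features(generate_phantom(PhantomSpec(seed=seed))).s_e
        hom = extract_features(
            generate_phantom(PhantomSpec(seed=seed, skew_shape_spread=0.0))
        ).s_e
        wins += het > hom
        deltas.append(het - hom)
    print(f"s_e(heterogeneous) > s_e(uniform) in {wins}/{N_PAIRS} seed pairs")

    pos = [0.1, 1.1, 2.1] + [5.0 + 0.4 * k for k in range(12)]
    neg = [0.2 * k for k in range(22)] + [10.1, 10.3, 10.5]
    roc = youden_cutoff(pos + neg, ["TRG01"] * 15 + ["TRG23"] * 25, bootstrap_reps=500)
    print(
        f"benchmark operating point (3 FN / 3 FP): SE={roc.sensitivity:.0%} "
        f"SP={roc.specificity:.0%} PPV={roc.ppv:.0%} NPV={roc.npv:.0%} "
        f"YI={roc.youden:.2f}"
    )
    out = {
        "pair_wins": wins,
        "n_pairs": N_PAIRS,
        "mean_s_e_delta": sum(deltas) / len(deltas),
        "benchmark": {
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "ppv": roc.ppv,
            "npv": roc.npv,
            "youden": roc.youden,
        },
        "bonferroni_threshold_18_tests": bonferroni_threshold(0.05, 18),
        "included_patients_85_cohort": count_included(85, [11, 24, 7, 3]),
    }
    (ROOT / "results" / "mechanism.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {ROOT / 'results' / 'mechanism.json'}")


if __name__ == "__main__":
    main()
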