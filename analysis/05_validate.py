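"""Validate every stage against ground truth it was not shown: exactness of
the bounded globally-optimal DBN search, calibration of the chi-square
penalty, edge recovery on known discrete networks, predictor/coefficient
recovery of the kinetic model, and end-to-end discrimination of
clock-driven from unregulated targets.

Writes results/validation.json.  Scaled-down replicate counts keep this a
quick summary; scripts/acceptance.py runs the full versions.
"""

import json
from pathlib import Path

from cyanoclock.experiments import (
    discrimination_experiment,
    mit_mdl_copy_agreement,
    oracle_agreement,
    predictor_recovery,
    structure_recovery,
)
from cyanoclock.network import null_positive_rate

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {
        "oracle_agreement": oracle_agreement(n_instances=20, seed=SEED),
        "null_positive_rate": {
            "rate": null_positive_rate(0.999, 500, 400, seed=SEED),
            "expected": 0.001,
        },
        "structure_recovery": structure_recovery(n_seeds=10, seed=SEED),
        "mit_mdl_copy_agreement": mit_mdl_copy_agreement(seed=SEED),
        "predictor_recovery": predictor_recovery(n_seeds=15, seed=SEED),
        "discrimination": discrimination_experiment(n_seeds=3, seed=SEED),
    }
    (OUT / "validation.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    print(
        "validation summary: "
        f"oracle agreement {summary['oracle_agreement']['fraction_identical']:.2f}; "
        f"null positive rate {summary['null_positive_rate']['rate']:.4f} (α=0.999); "
        f"edge F1 {summary['structure_recovery']['mean_f1']:.3f}; "
        f"predictor F1 {summary['predictor_recovery']['mean_f1']:.3f} "
        f"(coef rel err {summary['predictor_recovery']['mean_rel_coef_error']:.3f}); "
        f"discrimination acc driven/noise "
        f"{summary['discrimination']['accuracy_driven']:.2f}/"
        f"{summary['discrimination']['accuracy_noise']:.2f}; "
        f"details in {OUT / 'validation.json'}"
    )


if __name__ == "__main__":
    main()
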