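"""Generate the synthetic study: 12 entrained clock regulators sampled over
three 12 h light/dark cycles plus 24 h of continuous light (4 h spacing,
18 training + 6 test samples), with 10 clock-driven and 10 unregulated
target transcription factors.

Writes the expression matrices, ground truth and labels under results/data/.
"""

import json
from pathlib import Path

from cyanoclock.synthetic import simulate_study

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    clock, targets, truth, labels = simulate_study(seed=SEED)
    clock.write(OUT / "clock.tsv")
    targets.write(OUT / "targets.tsv")
    (OUT / "ground_truth.json").write_text(
        json.dumps(truth.to_json(), indent=1, sort_keys=True)
    )
    labels.rename("label").to_csv(OUT / "labels.tsv", sep="\t")
    n_train = (clock.samples["split"] == "train").sum()
    n_test = (clock.samples["split"] == "test").sum()
    print(
        f"simulated {len(clock.genes)} clock regulators and {len(targets.genes)} "
        f"targets over {clock.n_samples} samples ({n_train} L/D train, {n_test} LL test); "
        f"artifacts in {OUT}"
    )


if __name__ == "__main__":
    main()
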