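"""Reconstruct the clock gene network de novo: globally optimal order-1
dynamic Bayesian network under the Mutual Information Test score
(α = 0.999), with the MDL metric run alongside as a concordance check.

Reads results/data/clock.tsv; writes results/network/.
"""

from pathlib import Path

from cyanoclock.containers import ExpressionMatrix
from cyanoclock.network import MITConfig, learn_network
from cyanoclock.preprocessing import build_transitions, quantile_discretize, spline_upsample

OUT = Path("results/network")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    clock = ExpressionMatrix.read("results/data/clock.tsv")
    data = build_transitions(quantile_discretize(spline_upsample(clock, 2), 3))

    mit_net = learn_network(data, MITConfig(alpha=0.999, metric="mit"))
    mdl_net = learn_network(data, MITConfig(metric="mdl"))
    mit_net.write_edge_tsv(OUT / "edges_mit.tsv")
    mit_net.write_sif(OUT / "network_mit.sif")
    mit_net.write_dot(OUT / "network_mit.dot")
    mdl_net.write_edge_tsv(OUT / "edges_mdl.tsv")

    shared = set(mit_net.edges) & set(mdl_net.edges)
    print(
        f"MIT network: {len(mit_net.edges)} edges (total score "
        f"{mit_net.total_score:.2f}); MDL network: {len(mdl_net.edges)} edges; "
        f"{len(shared)} edges shared between the two metrics; artifacts in {OUT}"
    )


if __name__ == "__main__":
    main()
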