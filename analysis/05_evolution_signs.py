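#!/usr/bin/env python
"""End-to-end sign comparison on synthetic adaptive-evolution expression.

Generates wild-type vs evolved count tables whose log-fold-change signs
follow the shortest-path polarities from a knocked-out source regulator,
converts to TPM, computes observed signs and magnitudes, compares with
the network-predicted signs via the ranked precision curve <P>, and
assesses significance by shuffling the predictions (25,000 resamples).
Repeats at increasing noise to show the precision decay.  Writes
results/sign_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from irrnet.expression import (bootstrap_p, observed_signs, precision_curve,
                               tpm_convert)
from irrnet.synth import (SynthExpressionParams, SynthNetworkParams,
                          generate_expression, generate_network)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def run_once(net, src, noise):
    synth = generate_expression(net, SynthExpressionParams(
        source=src, perturbation="KO", effect=1.0, noise_sigma=noise,
        seed=SEED))
    tpm = pd.DataFrame(
        tpm_convert(synth.counts.to_numpy(), synth.lengths_kb.to_numpy()),
        index=synth.counts.index, columns=synth.counts.columns)
    rho = (tpm[synth.evo_columns].mean(axis=1)
           / tpm[synth.wt_columns].mean(axis=1))
    regulated = [g for g in rho.index
                 if g != src and synth.predicted[g] != "not_regulated"]
    obs = observed_signs(rho[regulated])
    mod = synth.predicted[regulated]
    cmp = precision_curve(obs["sign"], mod, obs["magnitude"])
    ranked = sorted(mod.index, key=lambda g: (-obs["magnitude"][g], g))
    boot = bootstrap_p("avg_precision",
                       {"obs": obs["sign"][ranked].to_numpy(),
                        "mod": mod[ranked].to_numpy(),
                        "n_threshold": cmp.n_threshold},
                       n_samp=25_000, seed=SEED)
    return cmp, boot


def main():
    OUT.mkdir(exist_ok=True)
    net = generate_network(SynthNetworkParams(
        n=40, edge_prob=0.08, repression_fraction=0.4, guarantee_root=True,
        seed=SEED))
    src = net.nodes[0]
    print(f"perturbed source: {src} (KO); {len(net)} genes")
    rows = []
    for noise in (0.0, 0.25, 0.5, 1.0, 2.0):
        cmp, boot = run_once(net, src, noise)
        print(f"noise sigma={noise:4.2f}: <P> = {cmp.avg_precision:.3f} over "
              f"{cmp.n_threshold} genes above |log fold change| 0.5; "
              f"bootstrap p = {boot.p_value:.4f} "
              f"(printed convention {boot.p_printed:.4f})")
        rows.append({"noise_sigma": noise,
                     "avg_precision": cmp.avg_precision,
                     "n_above_threshold": cmp.n_threshold,
                     "p_value": boot.p_value,
                     "p_printed": boot.p_printed})
    pd.DataFrame(rows).to_csv(OUT / "sign_comparison.csv", index=False)


if __name__ == "__main__":
    main()
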