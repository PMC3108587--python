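"""Mutation-drift-equilibrium envelope and excess-pi classification.

Simulates the equilibrium relationship between haplotype diversity (H) and
nucleotide diversity (pi) over a theta grid, then asks for every population
whether its observed pi is compatible with equilibrium given its observed H.
Admixed invasive populations are expected above the band; single-lineage
native populations within it.  Also writes a pi-vs-H figure with the band.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from parvapop.diversity import diversity_table
from parvapop.envelope import build_envelope, classify_excess_pi
from parvapop.popio import (
    collapse_haplotypes,
    read_alignment,
    read_popmap,
    screen_divergent_haplotypes,
)

DATA = Path("results/synthetic/long_distance")
OUT = Path("results/envelope")
SEED = 20110603


def main() -> None:
    aln = read_alignment(DATA / "alignment.fasta")
    popmap = read_popmap(DATA / "popmap.tsv")
    hap = collapse_haplotypes(aln, popmap)
    screen_divergent_haplotypes(hap)
    records = diversity_table(hap, popmap, B=500, seed=SEED)

    env = build_envelope(n=15, reps=1000, L=700, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    env.round(6).to_csv(OUT / "envelope.tsv", sep="\t", index=False)
    calls = classify_excess_pi(records, env)
    calls.round(5).to_csv(OUT / "excess_pi_calls.tsv", sep="\t")
    print(calls.round(4).to_string())
    inv_above = sum(
        (records.loc[p, "group"] == "invasive") and (v == "above")
        for p, v in calls["verdict"].items()
    )
    print(f"invasive populations above the equilibrium band: {inv_above}")

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(env["mean_H"], env["mean_pi"], "x-", color="grey", label="equilibrium mean")
    ax.fill_between(env["mean_H"], env["q05"], env["q95"], alpha=0.2, label="5-95% band")
    for grp, marker in (("native", "o"), ("invasive", "s")):
        sub = records[records["group"] == grp]
        ax.scatter(sub["H"], sub["pi"], marker=marker, label=grp)
    ax.set_xlabel("haplotype diversity H")
    ax.set_ylabel("nucleotide diversity pi")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "envelope.svg")
    print(f"figure -> {OUT/'envelope.svg'}")


if __name__ == "__main__":
    main()
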