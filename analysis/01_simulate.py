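"""Generate the synthetic study all later steps analyse.

Produces a transcriptome of mRNA-like and lncRNA-like sequences, a
cross-species miRNA set, planted target/mimic/none duplex sites,
negative-binomial counts with planted fold changes and co-expression
blocks, and the truth table — everything under results/sim/.
"""

import sys
from pathlib import Path

from hypolnc import core_io
from hypolnc.synthetic import SimConfig, simulate_all

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main(seed: int = 11) -> None:
    cfg = SimConfig(
        n_mrna=60, n_lncrna=60, n_mirna=20, conserved_fraction=0.6,
        n_target_sites=30, n_mimic_sites=20, n_none_sites=10,
        coexpr_blocks=((15, 2.0, 0.15),), de_fraction=0.05,
        len_dist={"mrna_meanlog": 6.8, "lncrna_meanlog": 6.3},
        seed=seed,
    )
    sim = simulate_all(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    core_io.write_fasta([(r.id, r.sequence) for r in sim.transcripts],
                        OUT / "transcripts.fasta")
    core_io.write_fasta([(m.id, m.sequence) for m in sim.mirnas],
                        OUT / "mirnas.fasta", alphabet="rna")
    with open(OUT / "mirna_species.tsv", "w") as fh:
        fh.write("mirna_id\tspecies\n")
        for m in sim.mirnas:
            fh.write(f"{m.id}\t{','.join(sorted(m.species))}\n")
    core_io.write_expression(sim.counts, OUT / "counts.tsv", OUT / "meta.tsv")
    core_io.write_expression(sim.fpkm, OUT / "fpkm.tsv")
    sim.truth.to_tsv(OUT / "truth.tsv")
    with open(OUT / "classes.tsv", "w") as fh:
        for t, c in sim.truth.class_labels.items():
            fh.write(f"{t}\t{c}\n")
    n_lnc = sum(1 for c in sim.truth.class_labels.values() if c == "lncRNA")
    print(f"simulated {len(sim.transcripts)} transcripts ({n_lnc} lncRNA-like), "
          f"{len(sim.mirnas)} miRNA records, "
          f"{len(sim.truth.planted_interactions)} planted duplex sites, "
          f"{len(sim.truth.planted_de)} DE transcripts -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 11)
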