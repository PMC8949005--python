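"""Rarefy the simulated community and compute alpha-diversity indices.

Samples are resampled to a common depth, then observed richness, Shannon,
Simpson evenness, Chao1, ACE and Good's coverage are tabulated per sample.
"""

from pathlib import Path

from pomnet.diversity import alpha_diversity_table
from pomnet.otu_table import rarefy, read_otu_table, write_otu_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    table = read_otu_table(RESULTS / "simulated" / "otu_table.tsv",
                           RESULTS / "simulated" / "sample_meta.tsv")
    depth = int(table.sample_sums().min())
    rare = rarefy(table, depth, seed=SEED)
    write_otu_table(rare, RESULTS / "rarefied_table.tsv")
    div = alpha_diversity_table(rare)
    div.to_csv(RESULTS / "diversity.tsv", sep="\t")
    print(f"rarefied {table.counts.shape[1]} samples to depth {depth}")
    print(div[["observed_otus", "shannon", "chao1",
               "goods_coverage"]].describe().round(3).loc[["mean", "min",
                                                           "max"]])


if __name__ == "__main__":
    main()
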