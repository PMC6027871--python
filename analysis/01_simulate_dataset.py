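"""Generate the synthetic study cohort and write its files.

Emulates the sampling design of the deer-hybridization panel: 7 + 6
individuals of two parental species (SK, WT) and 9 + 8 reciprocal F1 hybrids
(SW, WS), genotyped at 515 planted sites on a toy soft-masked reference —
50 clean diagnostic sites, 25 confounders (5 per screen failure mode),
400 shared polymorphic sites and 10 private-allele sites per group.

Writes reference.fasta, genotypes.vcf, popmap.tsv and truth.tsv under
results/data/ and prints the category budget.
"""

import argparse
from pathlib import Path

from diagmark.io import write_fasta, write_popmap, write_vcf
from diagmark.simulate import SimConfig, simulate_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    config = SimConfig(seed=args.seed)
    result = simulate_dataset(config)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.reference, args.out_dir / "reference.fasta")
    write_vcf(result.matrix, args.out_dir / "genotypes.vcf")
    write_popmap(result.popmap, args.out_dir / "popmap.tsv")
    result.truth.to_csv(args.out_dir / "truth.tsv", sep="\t", index=False)

    print(f"seed {args.seed}: {result.matrix.n_individuals} individuals "
          f"({', '.join(f'{g}={len(result.popmap.members(g))}' for g in result.popmap.groups)}) "
          f"x {result.matrix.n_sites} sites")
    print(result.truth["category"].value_counts().to_string())
    print(f"wrote reference/VCF/popmap/truth under {args.out_dir}")


if __name__ == "__main__":
    main()
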