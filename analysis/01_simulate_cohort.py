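#!/usr/bin/env python
"""Simulate the study cohort: orthologous upstream regions with planted truth.

Generates per-species genomes (one contig per gene: a 2 kb upstream region
followed by a synthetic gene body), plants one 90 bp conserved element per
gene at a gene-specific distance from the translation start (element
substitution rate 0.05 against a background of 0.35 per branch, four
comparator species), plants annotated repeats, and writes everything as
FASTA + GFF3 + BED. Also writes synthetic protein-similarity hit tables
(BLAST outfmt-6 dialect) for the orthology step, and a transcript set that
covers each element in full.

Outputs under results/cohort/.
"""

import argparse
from pathlib import Path

import numpy as np

from cnescan.io_formats import write_fasta
from cnescan.synthetic_data import (
    EvolutionConfig,
    PlantedElement,
    generate_ortholog_cohort,
    generate_pseudo_ortholog_pairs,
    generate_transcriptome,
)

MOTIF = "GCGTAACG"  # planted into every element; tested in 05


def write_hit_tables(cohort, outdir: Path, rng) -> None:
    """Synthetic protein-similarity tables: orthologs hit each other hardest."""
    genes = cohort.gene_ids
    for sp in cohort.genomes:
        if sp == cohort.config.central_species:
            continue
        for direction, (qs, ss) in {
            f"central_vs_{sp}": (genes, genes),
            f"{sp}_vs_central": (genes, genes),
        }.items():
            lines = []
            for q in qs:
                lines.append(
                    f"{q}\t{q}\t95.0\t300\t10\t1\t1\t300\t1\t300\t1e-120\t{300 + rng.integers(0, 40)}"
                )
                decoy = genes[int(rng.integers(0, len(genes)))]
                if decoy != q:
                    lines.append(
                        f"{q}\t{decoy}\t40.0\t120\t60\t5\t1\t120\t1\t120\t1e-8\t{40 + rng.integers(0, 20)}"
                    )
            (outdir / f"hits.{direction}.tsv").write_text("\n".join(lines) + "\n")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--length", type=int, default=2000, help="upstream span (bp)")
    parser.add_argument("--genes", type=int, default=10)
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    distances = rng.integers(100, args.length - 290, size=args.genes)
    per_gene = [
        [
            PlantedElement(
                distance_from_tls=int(d), length=90,
                element_substitution_rate=0.05, motif=MOTIF,
            )
        ]
        for d in distances
    ]
    config = EvolutionConfig(
        ancestor_length=args.length, n_genes=args.genes, seed=args.seed
    )
    cohort = generate_ortholog_cohort(config, planted_per_gene=per_gene,
                                      repeats_per_gene=1)
    cohort.write(args.outdir)
    write_hit_tables(cohort, args.outdir, rng)

    transcripts = generate_transcriptome(cohort, 1.0)
    write_fasta(transcripts, args.outdir / "transcripts.fa")

    pseudo = generate_pseudo_ortholog_pairs(cohort, seed=args.seed + 1)
    with open(args.outdir / "pseudo_pairs.tsv", "w") as fh:
        for a, b in pseudo:
            fh.write(f"{a}\t{b}\n")

    n_truth = sum(len(v) for v in cohort.truth.values())
    print(f"cohort written to {args.outdir}")
    print(f"  {args.genes} genes x {len(cohort.genomes)} species, {args.length} bp regions")
    print(f"  {n_truth} planted element copies (90 bp, motif {MOTIF})")
    print(f"  {sum(len(v) for v in cohort.repeats.values())} planted repeats")
    print(f"  {len(pseudo)} pseudo-ortholog pairs (derangement)")


if __name__ == "__main__":
    main()
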