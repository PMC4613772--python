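#!/usr/bin/env python
"""Discover conserved non-coding elements in the simulated cohort.

Loads the cohort written by 01_simulate_cohort.py through the package's own
format readers, pairs orthologs by reciprocal best hit from the hit tables,
extracts (repeat-masked) upstream regions, runs the calibrated two-phase
discovery, and evaluates the calls against the planted truth. Writes the CNE
set as BED + JSON-lines plus a stage-count report.
"""

import argparse
import json
from pathlib import Path

from cnescan.io_formats import read_bed, read_fasta, read_gff_genes, read_hits_table
from cnescan.orthology import reciprocal_best_hits
from cnescan.pipeline import RunConfig, run_discovery
from cnescan.upstream_extract import extract_cohort_regions


def load_regions(cohort_dir: Path, species: str, span: int):
    genome = read_fasta(cohort_dir / f"{species}.genome.fa")
    genes = read_gff_genes(cohort_dir / f"{species}.genes.gff3")
    repeat_file = cohort_dir / f"{species}.repeats.bed"
    repeats = read_bed(repeat_file) if repeat_file.exists() else None
    regions, removed = extract_cohort_regions(
        genes, genome, span=span, repeats=repeats, species=species
    )
    return regions, removed


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--outdir", type=Path, default=Path("results/discovery"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    manifest = dict(
        line.split("\t", 1)
        for line in (args.cohort / "manifest.txt").read_text().splitlines()
    )
    central_sp = manifest["central_species"].strip()
    span = int(manifest["ancestor_length"])
    species = [
        s.strip() for k, s in (
            line.split("\t", 1) for line in (args.cohort / "manifest.txt").read_text().splitlines()
        ) if k == "species" and s.strip() != central_sp
    ]

    central, removed = load_regions(args.cohort, central_sp, span)
    print(f"central regions: {len(central)} extracted, {len(removed)} removed")

    comps, omaps = {}, {}
    for sp in species:
        comps[sp], _ = load_regions(args.cohort, sp, span)
        fwd = read_hits_table(args.cohort / f"hits.central_vs_{sp}.tsv")
        rev = read_hits_table(args.cohort / f"hits.{sp}_vs_central.tsv")
        table = reciprocal_best_hits(fwd, rev, central_sp, sp)
        omaps[sp] = table.as_dict()
        print(f"  {sp}: {len(omaps[sp])} reciprocal-best-hit ortholog pairs")

    pseudo_pairs = [
        tuple(line.split("\t"))
        for line in (args.cohort / "pseudo_pairs.tsv").read_text().splitlines()
    ]

    result = run_discovery(
        central, comps, omaps, pseudo_pairs, RunConfig(span=span, seed=args.seed)
    )
    rep = result.report
    print(
        f"candidates {rep.counts['candidates']}, pseudo candidates "
        f"{rep.counts['pseudo_candidates']}, calibrated CCS threshold "
        f"{result.threshold:.3f}, detected {rep.counts['detected']}, "
        f"final CNEs {rep.counts['cnes']}"
    )

    # evaluate against planted truth
    truth_file = args.cohort / f"{central_sp}.truth.bed"
    if truth_file.exists():
        truth = read_bed(truth_file)
        recovered = 0
        for iv in truth:
            gene = iv.seq_id.split(".", 1)[1]
            if any(
                c.gene_id == gene
                and min(c.central_interval.end, iv.end)
                - max(c.central_interval.start, iv.start)
                >= 0.5 * len(iv)
                for c in result.cnes
            ):
                recovered += 1
        print(f"planted-element recovery: {recovered}/{len(truth)} "
              f"({100 * recovered / len(truth):.0f} %) at >=50 % overlap")
        rep.counts["planted_recovered"] = recovered
        rep.counts["planted_total"] = len(truth)

    with open(args.outdir / "cnes.bed", "w") as fh:
        for i, c in enumerate(result.cnes):
            fh.write(
                f"{central_sp}.{c.gene_id}\t{c.genomic_interval.start}\t"
                f"{c.genomic_interval.end}\tcne{i}\t{c.ccs:.4f}\n"
            )
    with open(args.outdir / "cnes.jsonl", "w") as fh:
        for i, c in enumerate(result.cnes):
            fh.write(json.dumps({
                "cne_id": f"cne{i}",
                "gene_id": c.gene_id,
                "central_interval": [c.central_interval.start, c.central_interval.end],
                "ccs": c.ccs,
                "supports": {
                    sp: [iv.start, iv.end, p] for sp, (iv, p) in c.supports.items()
                },
            }) + "\n")
    with open(args.outdir / "report.json", "w") as fh:
        json.dump(
            {"counts": rep.counts, "ccs_threshold": result.threshold,
             "coding_evalue_threshold": rep.coding_evalue_threshold
             if rep.coding_evalue_threshold != float("inf") else None},
            fh, indent=2,
        )
    print(f"wrote {args.outdir}/cnes.bed, cnes.jsonl, report.json")


if __name__ == "__main__":
    main()
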