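#!/usr/bin/env python
"""Motif over-representation in CNEs against matched control sets.

Builds a small PWM library (the planted element motif plus random matrices),
removes redundancy by complete-linkage clustering on Hellinger distances at
threshold 1.5 (median-entropy representatives), then calls each
representative over- or under-represented by comparing its binomial
upper-tail p-value in the CNE sequences against 100 geometry-matched control
sets (Ns mirrored into controls at the CNE's N positions).
"""

import argparse
import sys
from importlib import import_module
from pathlib import Path

import numpy as np
import pandas as pd

from cnescan.cne_features import matched_control_regions
from cnescan.motif_stats import PWM, cluster_pwms, overrepresentation_call, pwm_summaries

sys.path.insert(0, str(Path(__file__).parent))
discover = import_module("02_discover_cnes")
characterize = import_module("03_characterize_cnes")
simulate = import_module("01_simulate_cohort")


def _det_pwm(seq, pwm_id):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(seq), 4), 0.02)
    for i, c in enumerate(seq):
        mat[i, idx[c]] = 0.94
    return PWM(pwm_id, mat)


def _mirror_ns(control_seq: str, cne_seq: str) -> str:
    out = list(control_seq)
    for i, c in enumerate(cne_seq[: len(out)]):
        if c == "N":
            out[i] = "N"
    return "".join(out)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--discovery", type=Path, default=Path("results/discovery"))
    parser.add_argument("--outdir", type=Path, default=Path("results/motifs"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--control-sets", type=int, default=100)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    manifest = dict(
        line.split("\t", 1)
        for line in (args.cohort / "manifest.txt").read_text().splitlines()
    )
    central_sp = manifest["central_species"].strip()
    span = int(manifest["ancestor_length"])

    central, _ = discover.load_regions(args.cohort, central_sp, span)
    cnes = characterize.load_cnes(args.discovery / "cnes.jsonl")
    cne_seqs = [
        central[c.gene_id].sequence[c.central_interval.start : c.central_interval.end]
        for c in cnes
    ]

    rng = np.random.default_rng(args.seed)
    library = [_det_pwm(simulate.MOTIF, "planted_motif")]
    for i in range(30):
        library.append(PWM(f"rand{i:02d}", rng.dirichlet(np.full(4, 2.0), size=8)))
    clusters, reps = cluster_pwms(library, threshold=1.5)
    print(f"PWM library: {len(library)} matrices -> {len(reps)} representatives "
          f"at Hellinger threshold 1.5")

    control_sets = matched_control_regions(
        [(c.gene_id, c.central_interval) for c in cnes],
        central, n_sets=args.control_sets, seed=args.seed,
    )
    control_seq_sets = []
    for s in control_sets:
        seqs = []
        for (g, iv), cne_seq in zip(s, cne_seqs):
            seq = central[g].sequence[iv.start : iv.end]
            seqs.append(_mirror_ns(seq, cne_seq))
        control_seq_sets.append(seqs)

    rows = []
    for pwm in reps:
        call = overrepresentation_call(pwm, cne_seqs, control_seq_sets)
        entropy, gc_weight = pwm_summaries(pwm)
        rows.append(
            dict(pwm_id=pwm.id, entropy=entropy, gc_weight=gc_weight,
                 p_true=call.p_true, verdict=call.verdict)
        )
    table = pd.DataFrame(rows).sort_values("p_true")
    table.to_csv(args.outdir / "overrepresentation.tsv", sep="\t", index=False)
    n_over = int((table["verdict"] == "over").sum())
    n_under = int((table["verdict"] == "under").sum())
    print(f"{n_over} over-represented, {n_under} under-represented of {len(reps)}")
    print(table.head(5).to_string(index=False))
    print(f"wrote {args.outdir}/overrepresentation.tsv")


if __name__ == "__main__":
    main()
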