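"""Pairwise-difference panel for a focal mitochondrial genome.

Builds a synthetic 16.6 kb alignment in which each sequence carries a
known, disjoint set of substitutions relative to the focal sequence
(mimicking a panel of relatives at increasing divergence, with a little
missing data masked to N), ranks all sequences from most to least
dissimilar to the focal one, and verifies the planted structure is
recovered. Also tallies derived-allele read support over two synthetic
diagnostic-position tables at the study's observed tallies (10/22 and
11/52 reads matching the derived allele).

Writes results/mtdna/{ranked_differences.csv, diagnostic_support.csv}.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from paleotrail import mtdna, synth

ROOT = Path(__file__).resolve().parents[1]

# Panel names ordered from least to most divergent from the focal genome.
PANEL = ["Relative_A", "Relative_B", "Relative_C", "Relative_D", "Relative_E",
         "Modern_1", "Modern_2", "Outgroup"]
PLANTED = [9, 11, 14, 16, 19, 38, 41, 95]


def synthetic_diagnostic_table(n_matching, n_covered, n_sites, seed):
    """Diagnostic positions whose read tallies sum to the given counts."""
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(16_500, size=n_sites, replace=False)) + 1
    bases = "ACGT"
    statuses = ["derived"] * n_matching + ["ancestral"] * (n_covered - n_matching)
    rng.shuffle(statuses)
    site_reads = [[] for _ in range(n_sites)]
    for k, status in enumerate(statuses):
        site_reads[k % n_sites].append(status)
    sites = []
    for pos, reads in zip(positions, site_reads):
        derived = bases[rng.integers(4)]
        others = [b for b in bases if b != derived]
        observed = tuple(
            derived if s == "derived" else others[rng.integers(3)] for s in reads
        )
        sites.append(mtdna.DiagnosticSite(int(pos), derived, observed))
    return sites


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=ROOT / "results" / "mtdna")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    aln, planted = synth.make_alignment(
        n_seqs=len(PANEL) + 1, length=16_600,
        planted_diffs=dict(zip(PANEL, PLANTED)),
        missing_frac=0.02, seed=args.seed,
    )
    aln.names[0] = "Focal"
    ranked = mtdna.rank_dissimilarity(aln, "Focal")
    frame = pd.DataFrame(
        [{"other": r.seq_b, "n_diff": r.n_diff, "n_comparable": r.n_comparable,
          "planted": planted[r.seq_b]} for r in ranked]
    )
    frame.to_csv(out / "ranked_differences.csv", index=False)
    print("most to least dissimilar from Focal:")
    for r in ranked:
        print(f"  {r.seq_b:12s} {r.n_diff:4d} diffs over {r.n_comparable} sites")
    order_ok = [r.seq_b for r in ranked[::-1]] == PANEL
    print(f"planted divergence order recovered: {order_ok}")

    rows = []
    for lib, (match, cover) in {"LIB1": (10, 22), "LIB2": (11, 52)}.items():
        table = synthetic_diagnostic_table(match, cover, n_sites=12,
                                           seed=args.seed)
        n_match, n_cov = mtdna.diagnostic_allele_fraction(table)
        rows.append({"library": lib, "n_matching": n_match, "n_covered": n_cov})
        print(f"{lib}: {n_match}/{n_cov} reads match the derived allele")
    pd.DataFrame(rows).to_csv(out / "diagnostic_support.csv", index=False)


if __name__ == "__main__":
    main()
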