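"""Genome-size analysis of the 21 wild Musa accessions.

Reproduces the flow-cytometry arm of the characterization from the bundled
accession table and a simulated histogram panel:

* converts each printed 2C value to the monoploid genome size (Mbp) and
  checks the bundled integer column;
* computes the interspecific 2C variation within section Callimusa;
* reconstructs per-plant triplets from the printed mean ± SD and rebuilds
  the Bonferroni (alpha = 0.01) DNA-content letter grouping;
* correlates chromosome number with 2C content (tie-corrected Spearman),
  imputing the section-typical 2n = 20 for the two uncounted Callimusa
  accessions;
* simulates one histogram per accession at its printed 2C and re-estimates
  2C through the peak-detection pipeline.

Writes results/genome_size.csv and prints the headline numbers.
"""

import sys
from pathlib import Path

import pandas as pd

from charkit import flowsize as fs
from charkit import synthetic_data as sim
from charkit.datasets import load_accession_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    table = load_accession_table()

    # monoploid genome size from printed 2C
    table["mbp_recomputed"] = [
        fs.round_half_up(fs.pg_to_mbp(pg / 2)) for pg in table["two_c_pg"]
    ]
    n_match = int((table["mbp_recomputed"] == table["monoploid_mbp"]).sum())
    print(f"monoploid Mbp recomputed = printed for {n_match}/{len(table)} accessions")

    cal = table[table["section"] == "Callimusa"]["two_c_pg"]
    variation = (cal.max() - cal.min()) / cal.min() * 100
    print(f"Callimusa interspecific 2C variation: {variation:.1f}%")

    # Bonferroni letter grouping from reconstructed plant means
    samples = {
        row.itc_code: fs.reconstruct_plant_means(row.two_c_pg, row.sd_pg)
        for row in table.itertuples()
    }
    letters = fs.bonferroni_letter_groups(samples, alpha=0.01)
    n_groups = fs.n_letter_groups(letters)
    print(f"Bonferroni (alpha=0.01) DNA-content groups: {n_groups}")

    # Spearman 2n vs 2C with section-typical imputation for uncounted plants
    two_n = table["two_n"].fillna(20.0)
    r = fs.spearman_r(two_n.tolist(), table["two_c_pg"].tolist())
    print(f"Spearman r (2n vs 2C, n={len(table)}): {r:.2f}")

    # closed-loop histogram simulation at each printed 2C
    errors = []
    for i, row in enumerate(table.itertuples()):
        hist, truth = sim.gen_flow_histogram(
            sim.FlowSimSpec(true_2c_pg=row.two_c_pg, cv_percent=2.0, seed=seed + i)
        )
        musa, std = fs.detect_g1_peaks(hist, 2)
        est = fs.compute_2c(musa.mean, std.mean)
        errors.append(abs(est - row.two_c_pg) / row.two_c_pg * 100)
    table["sim_2c_error_pct"] = [round(e, 3) for e in errors]
    print(f"simulated-histogram 2C recovery: max error {max(errors):.2f}%")

    table["letters_recomputed"] = [
        "".join(sorted(letters[row.itc_code])) for row in table.itertuples()
    ]
    table.to_csv(OUT / "genome_size.csv", index=False)
    print(f"wrote {OUT / 'genome_size.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
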