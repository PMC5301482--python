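"""Optimize the mapping mismatch budget on cluster-bearing fixtures.

Dense editing clusters (here 5 edits within 90 bp, i.e. inside one read
length) unmap edited reads when the Hamming budget k is small, so the
mapping-based caller (method 1) loses exactly the clustered sites that the
consensus caller (method 2, the assembly-method stand-in) still sees.
This driver grids k = 2..10 on ten seeded fixtures, writes the per-seed
sensitivity/specificity tables, and reports the harmonic-mean pick per seed.
"""

from pathlib import Path

import pandas as pd

from mito_sre import calibrate, mapping, simulate

OUT = Path("results")
SEEDS = range(1, 11)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    picks = []
    for seed in SEEDS:
        seq, models = simulate.generate_genome(
            12000, 4, seed=seed, read_length=100, n_trna=0, n_rrna=0
        )
        truth = simulate.plant_events(
            seq, models, n_edits=30, sre_fraction=0.0, cluster_spec=(5, 90),
            n_snps=0, seed=seed + 100,
        )
        reads, _ = simulate.simulate_reads(
            seq, models, truth, depth=30, read_length=100,
            error_rate=0.005, seed=seed + 200,
        )
        genome = mapping.Genome("mito", seq)
        results = calibrate.run_grid(reads, genome, k_values=range(2, 11))
        table = calibrate.grid_table(results)
        table.insert(0, "seed", seed)
        rows.append(table)
        k = calibrate.select_k(results)
        picks.append(k)
        sens = {r.k: r.sensitivity for r in results}
        print(
            f"seed {seed}: sensitivity k=2 {sens[2]:.3f} -> k=7 {sens[7]:.3f}, "
            f"selected k = {k}"
        )
    pd.concat(rows).to_csv(OUT / "calibration_grid.tsv", sep="\t", index=False)
    in_band = sum(4 <= k <= 7 for k in picks)
    print(
        f"\nselected budgets: {picks}; {in_band}/10 fall in [4, 7] around the "
        f"planted cluster size of 5 — small budgets underestimate editing in "
        f"clustered regions, as expected"
    )


if __name__ == "__main__":
    main()
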