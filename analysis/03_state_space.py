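#!/usr/bin/env python
"""Enumerate the focal species' chromatin state space and classify it.

Builds all n^4 ordered tetramer complexes for the focal (7-paralog) species,
attaches energies from the additive table, groups complexes by dominant
paralog, traces a two-paralog dosage series, and classifies every paralog's
residue-49 chemistry (capstone detection).

Usage: python analysis/03_state_space.py [--in DIR] [--out DIR]
"""

import argparse
import json
from pathlib import Path

import archhist as ah
from archhist import catalog as cat
from archhist import state_space as ss


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="indir", type=Path,
                    default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth = json.loads((args.indir / "truth.json").read_text())
    aligned = cat.read_alignment(args.indir / "alignment.fasta")
    posmap = cat.build_position_map(aligned, truth["reference_id"])
    paralogs = truth["focal_paralogs"]
    backend = ah.load_energy_table(args.indir / "energy_table.tsv",
                                   reference_id="+".join([paralogs[0]] * 4))

    complexes = ah.enumerate_tetramers(paralogs, mode="ORDERED")
    energies = {c.key: backend.energy(c) for c in complexes}
    table = ss.complex_table(complexes, energies)
    table.to_csv(args.out / "complexes.tsv", sep="\t", index=False)
    summary = ah.summarize_state_space(complexes, energies)
    summary.to_csv(args.out / "state_space_summary.tsv", sep="\t", index=False)

    allrow = summary[summary.group == "ALL"].iloc[0]
    print(f"{truth['focal_species']}: {len(paralogs)} paralogs -> "
          f"{len(complexes)} ordered complexes "
          f"({len(paralogs)}^4 = {len(paralogs) ** 4})")
    print(f"ddG_bind spans [{allrow.bind_min:.2f}, {allrow.bind_max:.2f}], "
          f"ddG_tet spans [{allrow.tet_min:.2f}, {allrow.tet_max:.2f}] "
          "(relative to the reference homotetramer)")
    n_mixed = int((table.dominant == "MIXED").sum())
    print(f"dominant-paralog classes: {table.dominant.nunique() - 1} paralog-"
          f"dominated + MIXED ({n_mixed} complexes without a 3-of-4 majority)")

    # dosage gradation between the reference and the most destabilizing paralog
    stability = ah.homotetramer_stability(backend, paralogs)
    worst = max(stability, key=stability.get)
    series = ah.dosage_series(paralogs[0], worst, backend)
    series.to_csv(args.out / "dosage_series.tsv", sep="\t", index=False)
    print(f"dosage series {paralogs[0]} -> {worst}: mean ddG_tet per copy = "
          f"{(series.tet_mean.iloc[4] - series.tet_mean.iloc[0]) / 4:.3f} "
          "(exactly linear under the additive table)")

    calls = [ah.capstone_call(p, aligned.row(p), posmap) for p in paralogs]
    with open(args.out / "capstones.tsv", "w") as fh:
        fh.write("monomer_id\tresidue49\tclass\tbasis\n")
        for c in calls:
            fh.write(f"{c.monomer_id}\t{c.residue49}\t{c.clazz}\t{c.basis}\n")
    found = [c.monomer_id for c in calls if c.clazz == "CAPSTONE"]
    print(f"capstone calls among focal paralogs: {found or 'none'} "
          f"(planted: {truth['focal_capstones'] or 'none'})")


if __name__ == "__main__":
    main()
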