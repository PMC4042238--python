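"""Transposable-element composition of the locus.

Writes the per-species TE fixture as a RepeatMasker-style table, parses
it back, applies the shared-element filter (present in at least two
species including mouse), and tabulates which elements intersect each
exon and intron of the two overlapping lncRNA genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from rateshift import (
    make_feature_fixture,
    make_te_fixture,
    read_repeatmasker_out,
    shared_te_filter,
    te_feature_overlap,
)
from rateshift.synthetic import write_te_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results/te_composition"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tes = make_te_fixture()
    mouse = [t for t in tes if t.species == "mouse"]
    rm_path = args.out_dir / "mouse_locus.out"
    write_te_table(mouse, rm_path)
    parsed = read_repeatmasker_out(rm_path, ancient_only=True)
    print(f"RepeatMasker-style table -> {rm_path} ({len(parsed)} mobile elements parsed back)")

    groups = shared_te_filter(tes, min_species=2, required_species="mouse")
    shared = pd.DataFrame(
        {
            "symbol": [g.key for g in groups],
            "name": [g.name for g in groups],
            "class": [g.repeat_class for g in groups],
            "species": [", ".join(sorted(g.species)) for g in groups],
        }
    )
    shared.to_csv(args.out_dir / "shared_tes.tsv", sep="\t", index=False)
    print(f"\n{len(groups)} ancestral elements shared by >= 2 species including mouse:")
    print(shared.to_string(index=False))

    comp = te_feature_overlap(mouse, make_feature_fixture())
    comp.to_csv(args.out_dir / "composition.tsv", sep="\t", index=False)
    print("\nTE composition per gene element:")
    print(comp.to_string(index=False))


if __name__ == "__main__":
    main()
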