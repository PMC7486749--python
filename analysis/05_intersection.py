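"""Cross-experiment intersection and composition of the candidate species.

Intersects the suspension discriminant set with each knockdown set
(structural species identity), tabulates the class/category composition of
the results, and — as a check of the nomenclature layer against published
numbers — tabulates the bundled 42-species candidate panel, which must give
12 sphingolipids (6 Cer + 6 HexCer) and 30 glycerophospholipids
(8 PC, 7 PS).
"""

from pathlib import Path

from lipidisc.core import read_lipidomics_table
from lipidisc.datasets import candidate_species_list
from lipidisc.discriminants import (
    intersect_sets,
    knockdown_discriminants,
    suspension_discriminants,
)
from lipidisc.nomenclature import LipidCategory, tabulate_composition

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = BASE / "intersection"
    out.mkdir(parents=True, exist_ok=True)

    ds = read_lipidomics_table(BASE / "data" / "suspension.tsv")
    ds48 = read_lipidomics_table(BASE / "data" / "knockdown_48h.tsv")
    ds72 = read_lipidomics_table(BASE / "data" / "knockdown_72h.tsv")

    susp, _ = suspension_discriminants(ds)
    for target in ("siELOVL1", "siSLC27A1"):
        kd, _ = knockdown_discriminants(ds48, ds72, target)
        ix = intersect_sets(susp, kd)
        ix.to_frame().to_csv(out / f"suspension_x_{target}.tsv",
                             sep="\t", index=False)
        print(f"suspension ({len(susp)}) ∩ {target} ({len(kd)}) = {len(ix)} species")

    counts = tabulate_composition(candidate_species_list())
    print(f"\npublished 42-species candidate panel ({counts.n_unique} unique):")
    print(f"  sphingolipids: {counts.by_category[LipidCategory.SPHINGOLIPID]} "
          f"(Cer {counts.by_class['Cer']}, HexCer {counts.by_class['HexCer']})")
    print(f"  glycerophospholipids: "
          f"{counts.by_category[LipidCategory.GLYCEROPHOSPHOLIPID]} "
          f"(PC {counts.by_class['PC']}, PS {counts.by_class['PS']})")


if __name__ == "__main__":
    main()
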