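"""Suspension-induced differentiation: composition, clustering, PCA, sPLS-DA.

Reads results/data/suspension.tsv (run 01_simulate_datasets.py first),
normalizes to mol%, reports ceramide/hexosylceramide class dynamics,
clusters the Z-scored species matrix, runs PCA and a 3-component sPLS-DA
against the four differentiation classes, and extracts the discriminant
species accumulating during commitment (component 3) and differentiation
(component 2).  Recovery is checked against the generator's ground truth.
"""

import json
from pathlib import Path

import pandas as pd

from lipidisc.core import (
    class_composition,
    group_summary,
    hierarchical_cluster,
    normalize_molpct,
    pca,
    read_lipidomics_table,
    remove_near_zero_variance,
    zscore_by_species,
)
from lipidisc.discriminants import suspension_discriminants

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = read_lipidomics_table(BASE / "data" / "suspension.tsv")
    truth = json.loads((BASE / "data" / "truth.json").read_text())["suspension"]
    out = BASE / "suspension"
    out.mkdir(parents=True, exist_ok=True)

    molpct = normalize_molpct(ds)
    molpct.to_csv(out / "molpct.tsv", sep="\t")

    comp = class_composition(molpct)
    comp.to_csv(out / "class_composition.tsv", sep="\t")
    summary = group_summary(comp, ds.designs)
    summary.to_csv(out / "class_composition_by_group.tsv", sep="\t")
    means = summary["mean"]
    late = means.xs("control", level="treatment").loc[24.0]
    blocked = means.xs("PKCi", level="treatment").loc[24.0]
    diverging = (late - blocked).abs().nlargest(3).index
    print("classes diverging most between control and PKCi at 24 h (mol%):")
    for cls in diverging:
        print(f"  {cls}: control {late[cls]:.2f} vs PKCi {blocked[cls]:.2f}")

    z = zscore_by_species(molpct)
    link = hierarchical_cluster(z, axis="samples")
    pd.DataFrame(link.linkage, columns=["child_a", "child_b", "height", "size"]
                 ).to_csv(out / "sample_linkage.tsv", sep="\t", index=False)
    ordered = [link.labels[i] for i in link.leaf_order]
    (out / "sample_leaf_order.txt").write_text("\n".join(ordered) + "\n")
    print(f"\nclustering leaf order (first 6): {ordered[:6]}")

    filtered, nzv = remove_near_zero_variance(molpct)
    fit = pca(filtered, ncomp=3, scale=True)
    fit.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    print(f"PCA explained variance: "
          + ", ".join(f"{x:.1%}" for x in fit.explained_variance_ratio)
          + f" ({len(nzv.removed)} near-zero-variance species removed)")

    dset, model = suspension_discriminants(ds)
    dset.to_frame().to_csv(out / "discriminants.tsv", sep="\t", index=False)
    model.scores.to_csv(out / "splsda_scores.tsv", sep="\t")

    got = {s.canonical() for s in dset.species_set}
    planted_d = {p["species"] for p in truth["planted_species"]
                 if p["group"] == "differentiated"}
    planted_c = {p["species"] for p in truth["planted_species"]
                 if p["group"] == "commitment"}
    print(f"\ndiscriminant species: {len(got)} "
          f"(differentiated recovered {len(got & planted_d)}/{len(planted_d)}, "
          f"commitment recovered {len(got & planted_c)}/{len(planted_c)}, "
          f"false positives {len(got - planted_d - planted_c)})")


if __name__ == "__main__":
    main()
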