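"""Discriminant extraction rules, enrichment tests, set algebra."""

import statistics

import numpy as np
import pandas as pd
import pytest

from lipidisc.core import SampleDesign
from lipidisc.discriminants import (
    ACCUMULATED,
    DiscriminantRecord,
    DiscriminantSet,
    assign_suspension_classes,
    enriched_by_class_median,
    enriched_by_mean,
    intersect_sets,
    knockdown_discriminants,
    max_fold_change_table,
    suspension_discriminants,
)
from lipidisc.nomenclature import parse_species_annotation
from lipidisc.simulate import KnockdownEffects, simulate_knockdown, simulate_suspension


# ---------------------------------------------------------------------------
# class model

@pytest.mark.parametrize("tp,treatment,label", [
    (0, "control", "adherent"),
    (4, "control", "commitment"),
    (8, "control", "commitment"),
    (12, "control", "differentiated"),
    (24, "control", "differentiated"),
    (4, "PKCi", "inhibited"),
    (12, "PKCi", "inhibited"),
    (24, "PKCi", "inhibited"),
])
def test_suspension_class_model(tp, treatment, label):
    d = SampleDesign("s", timepoint=tp, treatment=treatment)
    assign_suspension_classes([d])
    assert d.class_label == label


def test_suspension_class_model_rejects_unknown():
    with pytest.raises(ValueError, match="unknown"):
        assign_suspension_classes([SampleDesign("s", timepoint=6, treatment="control")])
    with pytest.raises(ValueError, match="no timepoint"):
        assign_suspension_classes([SampleDesign("s")])


# ---------------------------------------------------------------------------
# enrichment

def test_median_enrichment_rules():
    mp = pd.DataFrame({
        "up": [3.0, 3.1, 1.0, 1.1, 0.9, 1.0, 1.0, 1.2],
        "flat": [1.0] * 8,
    }, index=[f"s{i}" for i in range(8)])
    labels = ["differentiated"] * 2 + ["adherent"] * 2 + ["commitment"] * 2 + \
        ["inhibited"] * 2
    enriched = enriched_by_class_median(mp, labels, "differentiated")
    assert bool(enriched["up"]) is True
    assert bool(enriched["flat"]) is False  # all-equal medians: strict > fails
    with pytest.raises(ValueError, match="no samples"):
        enriched_by_class_median(mp, labels, "missing")


def test_median_enrichment_matches_brute_force(rng):
    """Agreement with a per-species statistics.median loop on a 12×20 fixture."""
    mp = pd.DataFrame(rng.uniform(0.1, 5.0, size=(12, 20)),
                      index=[f"s{i}" for i in range(12)],
                      columns=[f"l{j}" for j in range(20)])
    labels = ["a", "b", "c", "d"] * 3
    got = enriched_by_class_median(mp, labels, "b")
    for col in mp.columns:
        meds = {
            cls: statistics.median(
                mp[col][np.array([x == cls for x in labels])])
            for cls in "abcd"
        }
        expected = all(meds["b"] > meds[c] for c in "acd")
        assert bool(got[col]) == expected


def test_mean_enrichment_and_fold_change():
    mp = pd.DataFrame({
        "double": [2.0, 2.0, 1.0, 1.0],
        "equal": [1.5, 1.5, 1.5, 1.5],
        "accumulated": [0.7, 0.9, 0.0, 0.0],
        "absent": [0.0, 0.0, 0.0, 0.0],
    }, index=["a1", "a2", "b1", "b2"])
    enriched, fc = enriched_by_mean(mp, ["a1", "a2"], ["b1", "b2"])
    assert bool(enriched["double"]) and fc["double"] == 2.0
    assert not enriched["equal"] and fc["equal"] == 1.0
    assert bool(enriched["accumulated"]) and fc["accumulated"] == ACCUMULATED
    assert not enriched["absent"] and np.isnan(fc["absent"])
    with pytest.raises(ValueError, match="non-empty"):
        enriched_by_mean(mp, [], ["b1"])


# ---------------------------------------------------------------------------
# extraction rules

def test_infinite_threshold_empties_the_set():
    ds, _ = simulate_suspension(seed=0)
    dset, _ = suspension_discriminants(ds, loading_threshold=np.inf)
    assert len(dset) == 0


def test_threshold_monotonicity():
    ds, _ = simulate_suspension(seed=0)
    low, _ = suspension_discriminants(ds, loading_threshold=0.01)
    high, _ = suspension_discriminants(ds, loading_threshold=0.05)
    assert high.species_set <= low.species_set


def test_sign_flip_does_not_change_extraction():
    """The |loading| + enrichment-direction rule ignores component signs."""
    from lipidisc.core import normalize_molpct, remove_near_zero_variance
    from lipidisc.splsda import fit_splsda

    ds, _ = simulate_suspension(seed=3)
    assign_suspension_classes(ds.designs)
    labels = [d.class_label for d in ds.designs]
    molpct = normalize_molpct(ds)
    X, _ = remove_near_zero_variance(molpct)
    model = fit_splsda(X, labels, ncomp=3, keepX=250)
    w = model.x_weights["comp2"]
    enriched = enriched_by_class_median(molpct, labels, "differentiated")
    direct = set(w.index[(w.abs() > 0.01) & enriched.reindex(w.index)])
    flipped = set(w.index[((-w).abs() > 0.01) & enriched.reindex(w.index)])
    assert direct == flipped


def test_knockdown_timepoint_of_max_fold_change():
    """Effects planted at 72 h only are reported with the 72 h timepoint."""
    effects = KnockdownEffects(n_elovl1=10, elovl1_timepoints=(72.0,),
                               n_accumulated=0, n_slc27a1=0)
    dss, truth = simulate_knockdown(effects=effects, seed=4)
    dset, _ = knockdown_discriminants(dss[48.0], dss[72.0], "siELOVL1")
    planted = truth.species_for("siELOVL1")
    recovered = [r for r in dset.records if r.species.canonical() in planted]
    assert len(recovered) >= 9
    assert all(r.timepoint == "72 h" for r in recovered)


def test_knockdown_accumulated_sentinel():
    dss, truth = simulate_knockdown(seed=0)
    dset, _ = knockdown_discriminants(dss[48.0], dss[72.0], "siELOVL1")
    control_zero = {p.species for p in truth.planted_species if p.control_zero}
    table = max_fold_change_table(dset)
    reported = table[table["species"].isin(control_zero)]
    assert len(reported) == len(control_zero) == 2
    assert (reported["fold_change"] == ACCUMULATED).all()
    assert (reported["max_fold_change"] == "Accumulated (48 and 72 h)").all()


def test_knockdown_requires_treatment_groups():
    dss, _ = simulate_knockdown(seed=0)
    ds48 = dss[48.0]
    keep = [d.sample_id for d in ds48.designs if d.treatment != "siScramble"]
    with pytest.raises(ValueError, match="siScramble"):
        knockdown_discriminants(ds48.subset_samples(keep), dss[72.0], "siELOVL1")


def test_max_fold_change_table_max_rule():
    rec = DiscriminantRecord(
        species=parse_species_annotation("Cer – 34:1:2"),
        source="siELOVL1", component=1, loading=0.2,
        enriched_in="siELOVL1", timepoint="72 h", fold_change=1.7,
    )
    table = max_fold_change_table(DiscriminantSet([rec]))
    assert table.loc[0, "max_fold_change"] == "1.7 (72 h)"


# ---------------------------------------------------------------------------
# intersection algebra

def _dset(*annotations, source="x"):
    return DiscriminantSet([
        DiscriminantRecord(parse_species_annotation(a), source, 1, 0.1, "g")
        for a in annotations
    ])


def test_intersection_algebra():
    a = _dset("Cer – 34:1:2", "PC – 16:0:0;18:1:0", source="suspension")
    b = _dset("Phosphatidylcholine – 16:0:0;18:1:0", "SM – 34:1:2",
              source="siELOVL1")
    ix = intersect_sets(a, b)
    assert len(ix) == 1 and "PC – 16:0:0;18:1:0" in ix
    # records from both sources are retained for shared species
    assert {r.source for r in ix.records} == {"suspension", "siELOVL1"}
    # subset, commutativity, idempotence
    assert intersect_sets(a, a).species_set == a.species_set
    assert intersect_sets(a, b).species_set == intersect_sets(b, a).species_set
    assert ix.species_set <= a.species_set and ix.species_set <= b.species_set
    disjoint = intersect_sets(a, _dset("TAG – 16:0:0;18:1:0;18:2:0"))
    assert len(disjoint) == 0
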