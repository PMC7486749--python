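"""Discriminant lipid extraction: loading thresholds, enrichment, intersections.

Two experiments nominate species:

* the suspension-differentiation time course, whose samples fall into four
  classes (adherent / commitment / differentiated / inhibited): a species is
  discriminant when it carries a sPLS-DA weight of magnitude > 0.01 on the
  component that separates the differentiated (component 2) or commitment
  (component 3) class *and* its class median mol% is strictly highest in
  that class;
* the knockdown time course ({siScramble, siELOVL1, siSLC27A1} × {48, 72} h,
  one sPLS-DA per timepoint): a species is discriminant for a knockdown when
  it carries weight magnitude > 0.01 on the relevant component (components
  1 and 2 for siELOVL1, component 2 for siSLC27A1) at either timepoint *and*
  its replicate-mean mol% exceeds the siScramble mean (fold change > 1; a
  positive mean over an undetectable control is flagged ``Accumulated``).

Intersecting the suspension set with each knockdown set yields the candidate
bioactive species.  All thresholds operate on |weight| combined with the
enrichment direction, which makes the sets invariant to the arbitrary sign
of the latent components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import LipidomicsDataset, SampleDesign, normalize_molpct, remove_near_zero_variance
from .nomenclature import LipidSpecies, parse_species_annotation
from .splsda import SPLSDAModel, fit_splsda, orient_component

#: fold-change sentinel: enriched but undetectable in the control
ACCUMULATED = "Accumulated"

SUSPENSION_CLASSES = ("adherent", "commitment", "differentiated", "inhibited")


def assign_suspension_classes(designs: Sequence[SampleDesign]) -> list[SampleDesign]:
    """Label suspension samples with their differentiation-stage class.

    0 h → adherent; untreated 4/8 h → commitment; untreated 12/24 h →
    differentiated; PKCi-treated 4–24 h → inhibited.  Labels are written to
    ``class_label`` in place and the list is returned.
    """
    for d in designs:
        if d.timepoint is None:
            raise ValueError(f"sample {d.sample_id!r} has no timepoint")
        tp = float(d.timepoint)
        pkci = (d.treatment or "").lower() in ("pkci", "gf109203x")
        if tp == 0:
            label = "adherent"
        elif pkci and tp in (4, 8, 12, 24):
            label = "inhibited"
        elif tp in (4, 8):
            label = "commitment"
        elif tp in (12, 24):
            label = "differentiated"
        else:
            raise ValueError(
                f"sample {d.sample_id!r}: unknown (timepoint, treatment) "
                f"combination ({d.timepoint}, {d.treatment})"
            )
        d.class_label = label
    return list(designs)


@dataclass(frozen=True)
class DiscriminantRecord:
    """One nominated species with the evidence that selected it."""

    species: LipidSpecies
    source: str                       # suspension | siELOVL1 | siSLC27A1
    component: int
    loading: float
    enriched_in: str
    timepoint: str | None = None      # e.g. "72 h", "48 and 72 h"
    fold_change: float | str | None = None  # > 0, ACCUMULATED, or None

    def __post_init__(self) -> None:
        if isinstance(self.fold_change, (int, float)) and not self.fold_change > 0:
            raise ValueError(f"fold_change must be > 0, got {self.fold_change}")


@dataclass
class DiscriminantSet:
    """A collection of discriminant records and its unique-species set."""

    records: list[DiscriminantRecord] = field(default_factory=list)

    @property
    def species_set(self) -> frozenset[LipidSpecies]:
        return frozenset(r.species for r in self.records)

    def __len__(self) -> int:
        return len(self.species_set)

    def __contains__(self, item) -> bool:
        if isinstance(item, str):
            item = parse_species_annotation(item)
        return item in self.species_set

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in sorted(self.records, key=lambda r: r.species.canonical()):
            fc = r.fold_change
            rows.append({
                "species": r.species.canonical(),
                "source": r.source,
                "component": r.component,
                "loading": r.loading,
                "enriched_in": r.enriched_in,
                "timepoint": r.timepoint if r.timepoint is not None else "n/a",
                "fold_change": fc if fc is not None else "n/a",
            })
        return pd.DataFrame(
            rows, columns=["species", "source", "component", "loading",
                           "enriched_in", "timepoint", "fold_change"],
        )


# ---------------------------------------------------------------------------
# enrichment tests

def enriched_by_class_median(
    molpct: pd.DataFrame,
    labels: Sequence[str],
    target_class: str,
    comparator: Literal["each", "pooled"] = "each",
) -> pd.Series:
    """Per-species flag: is the target class's median strictly the highest?

    ``each`` (default) requires the target median to exceed the median of
    every other class; ``pooled`` compares against the median of all other
    samples pooled.  Ties are not enrichment.
    """
    labels = pd.Index([str(x) for x in labels])
    if target_class not in set(labels):
        raise ValueError(f"class {target_class!r} has no samples")
    tmed = molpct.loc[np.asarray(labels == target_class)].median(axis=0)
    if comparator == "pooled":
        other = molpct.loc[np.asarray(labels != target_class)].median(axis=0)
        return tmed > other
    ok = pd.Series(True, index=molpct.columns)
    for cls in sorted(set(labels) - {target_class}):
        omed = molpct.loc[np.asarray(labels == cls)].median(axis=0)
        ok &= tmed > omed
    return ok


def enriched_by_mean(
    molpct: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[pd.Series, pd.Series]:
    """Replicate-mean enrichment of group A over group B, with fold changes.

    Returns ``(enriched, fold_change)`` per species.  fold_change is
    mean(A)/mean(B); when mean(B) = 0 with mean(A) > 0 the species is
    enriched with the :data:`ACCUMULATED` sentinel; when both means are 0
    the species is not enriched and the fold change is NaN (undefined).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    a = molpct.loc[list(group_a)].mean(axis=0)
    b = molpct.loc[list(group_b)].mean(axis=0)
    both_zero = (a == 0) & (b == 0)
    accumulated = (b == 0) & (a > 0)
    regular = ~both_zero & ~accumulated
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    fc = pd.Series(index=molpct.columns, dtype=object)
    fc[regular] = ratio[regular].astype(float)
    fc[accumulated] = ACCUMULATED
    fc[both_zero] = math.nan
    enriched = (regular & (ratio > 1)) | accumulated
    return enriched, fc


# ---------------------------------------------------------------------------
# suspension experiment

def suspension_discriminants(
    ds: LipidomicsDataset,
    ncomp: int = 3,
    keepX: int = 250,
    loading_threshold: float = 0.01,
    comparator: Literal["each", "pooled"] = "each",
    rule: Literal["absolute", "signed"] = "absolute",
) -> tuple[DiscriminantSet, SPLSDAModel]:
    """Nominate species accumulating during commitment/differentiation.

    Fits a 3-component sPLS-DA on the mol% table (unit-scaled, near-zero
    variance species removed) against the four suspension classes, then
    takes the union of

    * component 2 species with |weight| > threshold that are
      median-enriched in the differentiated class, and
    * component 3 species with |weight| > threshold that are
      median-enriched in the commitment class.

    ``rule="signed"`` instead orients each component toward its class and
    requires the signed weight to exceed the threshold.
    """
    designs = ds.designs
    if any(d.class_label is None for d in designs):
        assign_suspension_classes(designs)
    labels = [d.class_label for d in designs]
    molpct = normalize_molpct(ds)
    X, _ = remove_near_zero_variance(molpct)
    model = fit_splsda(X, labels, ncomp=ncomp, keepX=keepX)
    for comp, cls in ((1, "adherent"), (2, "differentiated"), (3, "commitment")):
        if comp <= ncomp:
            model = orient_component(model, comp, cls)

    records = []
    for comp, cls in ((2, "differentiated"), (3, "commitment")):
        if comp > ncomp:
            continue
        w = model.x_weights[f"comp{comp}"]
        if rule == "signed":
            passing = w > loading_threshold
        else:
            passing = w.abs() > loading_threshold
        enriched = enriched_by_class_median(molpct, labels, cls, comparator)
        hits = passing & enriched.reindex(w.index, fill_value=False)
        for name in w.index[hits]:
            records.append(DiscriminantRecord(
                species=parse_species_annotation(name),
                source="suspension",
                component=comp,
                loading=float(w[name]),
                enriched_in=cls,
            ))
    return DiscriminantSet(records), model


# ---------------------------------------------------------------------------
# knockdown experiment

_TARGET_COMPONENTS = {"siELOVL1": (1, 2), "siSLC27A1": (2,)}


def _fc_value(fc) -> float:
    """Sort key: ACCUMULATED outranks any numeric fold change."""
    if fc == ACCUMULATED:
        return math.inf
    if fc is None or (isinstance(fc, float) and math.isnan(fc)):
        return -math.inf
    return float(fc)


def _format_timepoints(tps: Sequence[float]) -> str:
    tps = sorted(int(t) for t in tps)
    if len(tps) == 1:
        return f"{tps[0]} h"
    return " and ".join(str(t) for t in tps) + " h"


def knockdown_discriminants(
    ds48: LipidomicsDataset,
    ds72: LipidomicsDataset,
    target: str,
    control: str = "siScramble",
    ncomp: int = 3,
    keepX: int = 250,
    loading_threshold: float = 0.01,
    components: Sequence[int] | None = None,
    rule: Literal["absolute", "signed"] = "absolute",
) -> tuple[DiscriminantSet, dict[float, SPLSDAModel]]:
    """Nominate species accumulating under a knockdown versus the control.

    One sPLS-DA per timepoint (treatment labels), union over the target's
    components × {48 h, 72 h} of species with |weight| > threshold that are
    replicate-mean enriched in the target versus the control.  Each record
    reports the timepoint of the species' maximal fold change (the
    ``Accumulated`` sentinel outranks any numeric value).
    """
    if components is None:
        try:
            components = _TARGET_COMPONENTS[target]
        except KeyError:
            raise ValueError(
                f"no default component set for target {target!r}; pass components="
            ) from None

    models: dict[float, SPLSDAModel] = {}
    qualifying: dict[str, list[tuple[int, float, float]]] = {}
    fc_by_tp: dict[float, pd.Series] = {}

    for tp, ds in ((48.0, ds48), (72.0, ds72)):
        treatments = [d.treatment for d in ds.designs]
        present = set(treatments)
        for needed in (target, control):
            if needed not in present:
                raise ValueError(f"{int(tp)} h dataset lacks treatment {needed!r}")
        molpct = normalize_molpct(ds)
        X, _ = remove_near_zero_variance(molpct)
        model = fit_splsda(X, treatments, ncomp=ncomp, keepX=keepX)
        for comp in components:
            model = orient_component(model, comp, target)
        models[tp] = model

        ids = np.array(ds.sample_ids)
        tmask = np.array([t == target for t in treatments])
        cmask = np.array([t == control for t in treatments])
        enriched, fc = enriched_by_mean(molpct, ids[tmask], ids[cmask])
        fc_by_tp[tp] = fc
        for comp in components:
            w = model.x_weights[f"comp{comp}"]
            passing = (w > loading_threshold) if rule == "signed" else (
                w.abs() > loading_threshold)
            hits = passing & enriched.reindex(w.index, fill_value=False)
            for name in w.index[hits]:
                qualifying.setdefault(name, []).append((comp, float(w[name]), tp))

    records = []
    for name, evidence in qualifying.items():
        comp, loading, _ = max(evidence, key=lambda e: abs(e[1]))
        fc48 = fc_by_tp[48.0].get(name, math.nan)
        fc72 = fc_by_tp[72.0].get(name, math.nan)
        best = max((_fc_value(fc48), 48.0), (_fc_value(fc72), 72.0))[0]
        if best == math.inf:
            tps = [tp for tp, fc in ((48, fc48), (72, fc72)) if fc == ACCUMULATED]
            fc_out: float | str = ACCUMULATED
            tp_out = _format_timepoints(tps)
        else:
            tp_out = "48 h" if _fc_value(fc48) >= _fc_value(fc72) else "72 h"
            fc_out = max(_fc_value(fc48), _fc_value(fc72))
        records.append(DiscriminantRecord(
            species=parse_species_annotation(name),
            source=target,
            component=comp,
            loading=loading,
            enriched_in=target,
            timepoint=tp_out,
            fold_change=fc_out,
        ))
    return DiscriminantSet(records), models


def max_fold_change_table(dset: DiscriminantSet) -> pd.DataFrame:
    """Report each species' maximal fold change with its timepoint.

    Produces a published-table-style listing: ``1.7 (72 h)`` or
    ``Accumulated (48 and 72 h)``.
    """
    rows = []
    for r in sorted(dset.records, key=lambda r: r.species.canonical()):
        if r.fold_change == ACCUMULATED:
            formatted = f"{ACCUMULATED} ({r.timepoint})"
        elif r.fold_change is None:
            formatted = "n/a"
        else:
            formatted = f"{r.fold_change:g} ({r.timepoint})"
        rows.append({
            "species": r.species.canonical(),
            "source": r.source,
            "fold_change": r.fold_change,
            "timepoint": r.timepoint,
            "max_fold_change": formatted,
        })
    return pd.DataFrame(
        rows, columns=["species", "source", "fold_change", "timepoint",
                       "max_fold_change"],
    )


def intersect_sets(a: DiscriminantSet, b: DiscriminantSet) -> DiscriminantSet:
    """Species present in both sets (canonical structural identity).

    Records from both sources are kept for every shared species.
    """
    shared = a.species_set & b.species_set
    records = [r for r in a.records + b.records if r.species in shared]
    return DiscriminantSet(records)
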