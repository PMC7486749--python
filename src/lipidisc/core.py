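"""Lipidomics tables: ingestion, mol% normalization, Z-scores, clustering, PCA.

The in-memory convention throughout the package is a pandas DataFrame of
shape samples × species whose index holds sample ids and whose columns hold
canonical species annotations (see :mod:`~lipidisc.nomenclature`).  Amounts
arrive as picomoles; analysis happens on mol% — each species expressed as a
percentage of the total lipid amount of its sample — which removes the
arbitrary per-sample input scale of shotgun lipidomics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .nomenclature import LipidSpecies, parse_species_annotation, LipidParseError

logger = logging.getLogger("lipidisc")


@dataclass
class SampleDesign:
    """Design annotation of one sample (time course or screen-free)."""

    sample_id: str
    experiment: str = "suspension"
    timepoint: float | None = None
    treatment: str | None = None
    replicate: int = 1
    class_label: str | None = None


@dataclass
class LipidomicsDataset:
    """Samples × species pmol matrix plus per-sample design labels."""

    designs: list[SampleDesign]
    species: list[LipidSpecies]
    abundance: np.ndarray  # (n_samples, n_species) pmol, non-negative

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.designs), len(self.species)):
            raise ValueError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.designs)} designs × {len(self.species)} species"
            )
        if np.any(self.abundance < 0):
            raise ValueError("abundance matrix contains negative entries")
        ids = [d.sample_id for d in self.designs]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values are not unique")

    @property
    def sample_ids(self) -> list[str]:
        return [d.sample_id for d in self.designs]

    @property
    def species_names(self) -> list[str]:
        return [s.canonical() for s in self.species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=self.sample_ids, columns=self.species_names
        )

    def subset_samples(self, keep: Sequence[str]) -> "LipidomicsDataset":
        keep = list(keep)
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        idx = [pos[k] for k in keep]
        return LipidomicsDataset(
            [self.designs[i] for i in idx], list(self.species), self.abundance[idx]
        )


# ---------------------------------------------------------------------------
# ingestion

_LONG_REQUIRED = ("sample", "lipid", "pmol")
_SIDE_REQUIRED = ("sample",)


def _design_from_row(row: pd.Series) -> SampleDesign:
    def get(col, default=None):
        v = row.get(col, default)
        return default if pd.isna(v) else v

    tp = get("timepoint")
    return SampleDesign(
        sample_id=str(row["sample"]),
        experiment=str(get("experiment", "suspension")),
        timepoint=float(tp) if tp is not None else None,
        treatment=(str(get("treatment")) if get("treatment") is not None else None),
        replicate=int(get("replicate", 1)),
        class_label=(str(get("class_label")) if get("class_label") is not None else None),
    )


def read_design_table(path) -> list[SampleDesign]:
    """Read a design sidecar (TSV/CSV: sample, experiment, timepoint, treatment, replicate)."""
    df = _read_delim(path)
    missing = [c for c in _SIDE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"design file {path} missing columns: {missing}")
    return [_design_from_row(row) for _, row in df.iterrows()]


def _read_delim(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_lipidomics_table(
    path,
    layout: Literal["long", "wide"] = "long",
    design_path=None,
) -> LipidomicsDataset:
    """Read a lipidomics abundance table.

    Long layout: columns ``sample``, ``lipid``, ``pmol`` (a ``class`` column,
    if present, is ignored — the class is recovered by parsing the
    annotation) plus optional design columns (experiment, timepoint,
    treatment, replicate).  Duplicate (sample, lipid) rows are summed with a
    logged warning; absent pairs are zeros, as shotgun lipidomics reports
    only detected species.

    Wide layout: first column ``lipid``, one column per sample, with a
    mandatory design sidecar naming every sample column.
    """
    df = _read_delim(path)
    if layout == "long":
        missing = [c for c in _LONG_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {missing}")
        errors = []
        parsed: dict[str, LipidSpecies] = {}
        for rownum, ann in zip(df.index, df["lipid"]):
            if ann in parsed:
                continue
            try:
                parsed[ann] = parse_species_annotation(str(ann))
            except LipidParseError as exc:
                errors.append(f"row {rownum + 2}: {exc}")
        if errors:
            raise LipidParseError(
                f"{path}: {len(errors)} unparseable annotation(s):\n"
                + "\n".join(errors[:10])
            )
        ndup = df.duplicated(subset=["sample", "lipid"]).sum()
        if ndup:
            logger.warning("%s: %d duplicate (sample, lipid) rows summed", path, ndup)
        wide = (
            df.pivot_table(index="sample", columns="lipid", values="pmol",
                           aggfunc="sum", fill_value=0.0, sort=False)
        )
        if design_path is not None:
            designs = read_design_table(design_path)
            order = [d.sample_id for d in designs]
            missing_samples = sorted(set(wide.index) - set(order))
            if missing_samples:
                raise ValueError(
                    f"{path}: samples absent from design sidecar: {missing_samples}"
                )
            wide = wide.reindex(order, fill_value=0.0)
        else:
            design_cols = [c for c in
                           ("experiment", "timepoint", "treatment", "replicate",
                            "class_label") if c in df.columns]
            meta = df.drop_duplicates(subset="sample").set_index("sample")
            designs = []
            for sid in wide.index:
                row = meta.loc[sid, design_cols] if design_cols else pd.Series()
                row = pd.concat([pd.Series({"sample": sid}), row])
                designs.append(_design_from_row(row))
        species = [parsed[ann] for ann in wide.columns]
        return LipidomicsDataset(designs, species, wide.to_numpy(dtype=float))

    if layout == "wide":
        if design_path is None:
            raise ValueError("wide layout requires a design sidecar file")
        if "lipid" not in df.columns:
            raise ValueError(f"{path}: wide layout requires a 'lipid' column")
        designs = read_design_table(design_path)
        sample_cols = [c for c in df.columns if c != "lipid"]
        known = {d.sample_id for d in designs}
        unknown = sorted(set(sample_cols) - known)
        if unknown:
            raise ValueError(f"{path}: sample columns absent from sidecar: {unknown}")
        species = [parse_species_annotation(str(a)) for a in df["lipid"]]
        mat = df[[d.sample_id for d in designs]].to_numpy(dtype=float).T
        return LipidomicsDataset(designs, species, mat)

    raise ValueError(f"unknown layout {layout!r}")


def write_lipidomics_long(ds: LipidomicsDataset, path) -> None:
    """Write a dataset as a long TSV that :func:`read_lipidomics_table` accepts."""
    rows = []
    for i, d in enumerate(ds.designs):
        for j, sp in enumerate(ds.species):
            rows.append({
                "sample": d.sample_id, "lipid": sp.canonical(),
                "class": sp.lipid_class, "pmol": ds.abundance[i, j],
                "experiment": d.experiment, "timepoint": d.timepoint,
                "treatment": d.treatment, "replicate": d.replicate,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization and composition

def normalize_molpct(ds: LipidomicsDataset) -> pd.DataFrame:
    """mol% of total sample lipid: 100 · pmol / Σ pmol, per sample row."""
    totals = ds.abundance.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [ds.sample_ids[i] for i in zero]
        raise ValueError(f"sample(s) with zero total lipid: {bad}")
    mp = 100.0 * ds.abundance / totals[:, None]
    return pd.DataFrame(mp, index=ds.sample_ids, columns=ds.species_names)


def class_composition(molpct: pd.DataFrame) -> pd.DataFrame:
    """Class-level mol% table (classes × samples); columns sum to 100."""
    classes = [parse_species_annotation(c).lipid_class for c in molpct.columns]
    out = molpct.T.groupby(pd.Index(classes, name="lipid_class"), sort=True).sum()
    return out


def group_summary(
    table: pd.DataFrame, designs: Sequence[SampleDesign],
    by: tuple[str, ...] = ("timepoint", "treatment"),
) -> pd.DataFrame:
    """Mean and SD of each feature per design group (e.g. timepoint × treatment).

    ``table`` is features × samples (as produced by :func:`class_composition`).
    """
    meta = pd.DataFrame(
        {k: [getattr(d, k) for d in designs] for k in by},
        index=[d.sample_id for d in designs],
    )
    long = table.T.join(meta)
    grouped = long.groupby(list(by), dropna=False)[list(table.index)]
    return pd.concat({"mean": grouped.mean(), "sd": grouped.std(ddof=1)}, axis=1)


def zscore_by_species(
    molpct: pd.DataFrame,
    on_zero_sd: Literal["drop", "error"] = "drop",
) -> pd.DataFrame:
    """Standardize each species across samples ((x − mean)/SD, n−1 denominator).

    Zero-SD species are dropped with a logged warning (or raise, per
    ``on_zero_sd``) so downstream heatmaps and clustering stay finite.
    """
    if molpct.shape[0] < 2:
        raise ValueError("Z-scoring requires at least 2 samples")
    sd = molpct.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        if on_zero_sd == "error":
            raise ValueError(f"zero-SD species: {constant}")
        logger.warning("dropping %d zero-SD species before Z-scoring", len(constant))
    keep = sd[sd > 0].index
    centered = molpct[keep] - molpct[keep].mean(axis=0)
    return centered / sd[keep]


# ---------------------------------------------------------------------------
# hierarchical clustering (Euclidean, complete linkage, deterministic ties)

class LinkageResult(NamedTuple):
    """Agglomeration record in scipy linkage layout plus a leaf order."""

    linkage: np.ndarray   # (n-1, 4): child a, child b, height, cluster size
    leaf_order: list[int]
    labels: list[str]


def hierarchical_cluster(
    matrix: pd.DataFrame | np.ndarray,
    axis: Literal["samples", "species"] = "samples",
) -> LinkageResult:
    """Complete-linkage agglomerative clustering with Euclidean distances.

    Ties in merge height are broken toward the pair whose (sorted) smallest
    member labels are lexicographically least, and each internal node puts
    the subtree containing the smallest label on the left — so the tree and
    the leaf order are invariant to input row permutation (for unlabeled
    arrays the labels are the stringified original indices).
    """
    if isinstance(matrix, pd.DataFrame):
        data = matrix.to_numpy(dtype=float)
        labels = list(matrix.index if axis == "samples" else matrix.columns)
    else:
        data = np.asarray(matrix, dtype=float)
        labels = None
    if axis == "species":
        data = data.T
    n = data.shape[0]
    if n < 2:
        raise ValueError("clustering requires at least 2 items")
    if np.isnan(data).any():
        raise ValueError("clustering input contains NaN entries")
    if labels is None:
        labels = [str(i) for i in range(n)]

    diff = data[:, None, :] - data[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))

    # active cluster state; canonical order keyed by smallest member label
    min_label: dict[int, str] = {i: str(labels[i]) for i in range(n)}
    dmat: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    children: dict[int, tuple[int, int]] = {}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    linkage_rows = []
    next_id = n
    active = set(range(n))

    def pair_key(i: int, j: int) -> tuple:
        a, b = sorted((min_label[i], min_label[j]))
        return (dmat[(min(i, j), max(i, j))], a, b)

    while len(active) > 1:
        best = min(
            ((i, j) for i in active for j in active if i < j),
            key=lambda p: pair_key(*p),
        )
        i, j = best
        h = dmat[(i, j)]
        # left child = subtree holding the smallest label
        left, right = (i, j) if min_label[i] <= min_label[j] else (j, i)
        children[next_id] = (left, right)
        sizes[next_id] = sizes[i] + sizes[j]
        linkage_rows.append([left, right, h, sizes[next_id]])
        min_label[next_id] = min(min_label[i], min_label[j])
        active.discard(i)
        active.discard(j)
        for k in active:
            dmat[(min(k, next_id), max(k, next_id))] = max(
                dmat[(min(i, k), max(i, k))], dmat[(min(j, k), max(j, k))]
            )
        active.add(next_id)
        next_id += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    order = leaves(next_id - 1)
    return LinkageResult(np.array(linkage_rows, dtype=float), order, labels)


# ---------------------------------------------------------------------------
# near-zero-variance filter

class NZVReport(NamedTuple):
    removed: list[str]
    reasons: dict[str, str]


def remove_near_zero_variance(
    matrix: pd.DataFrame,
    freq_cut: float = 95 / 5,
    unique_cut: float = 0.10,
    mode: Literal["freq", "variance"] = "freq",
    var_tol: float = 1e-12,
) -> tuple[pd.DataFrame, NZVReport]:
    """Drop near-zero-variance predictors before multivariate analysis.

    ``freq`` mode replicates the common screening rule: a feature is removed
    when the frequency ratio of its most common to second most common value
    exceeds ``freq_cut`` (default 95/5) *and* the fraction of distinct values
    is below ``unique_cut`` (default 10%); constant features are always
    removed.  ``variance`` mode simply drops features with variance below
    ``var_tol``.
    """
    removed: list[str] = []
    reasons: dict[str, str] = {}
    n = matrix.shape[0]
    for col in matrix.columns:
        vals = matrix[col].to_numpy()
        _, counts = np.unique(vals, return_counts=True)
        if counts.size == 1:
            removed.append(col)
            reasons[col] = "zero variance (constant)"
            continue
        if mode == "variance":
            if float(np.var(vals, ddof=1)) < var_tol:
                removed.append(col)
                reasons[col] = f"variance below {var_tol}"
            continue
        counts_sorted = np.sort(counts)[::-1]
        freq_ratio = counts_sorted[0] / counts_sorted[1]
        unique_frac = counts.size / n
        if freq_ratio > freq_cut and unique_frac < unique_cut:
            removed.append(col)
            reasons[col] = (
                f"freq ratio {freq_ratio:.1f} > {freq_cut:.1f} and "
                f"unique fraction {unique_frac:.2f} < {unique_cut:.2f}"
            )
    if removed:
        logger.warning("near-zero-variance filter removed %d species", len(removed))
    return matrix.drop(columns=removed), NZVReport(removed, reasons)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: pd.DataFrame         # samples × components
    loadings: pd.DataFrame       # species × components
    explained_variance_ratio: np.ndarray
    means: pd.Series = field(repr=False, default=None)
    scales: pd.Series = field(repr=False, default=None)


def pca(matrix: pd.DataFrame, ncomp: int = 3, scale: bool = True) -> PCAResult:
    """PCA of a samples × species table (mean-centered, optionally unit-scaled).

    Scaling uses the sample SD (n−1); zero-SD columns must be removed first
    (see :func:`remove_near_zero_variance`).
    """
    n, p = matrix.shape
    if not (1 <= ncomp <= min(n - 1, p)):
        raise ValueError(f"ncomp must be in [1, {min(n - 1, p)}], got {ncomp}")
    means = matrix.mean(axis=0)
    X = matrix - means
    if scale:
        scales = matrix.std(axis=0, ddof=1)
        if (scales == 0).any():
            bad = scales[scales == 0].index.tolist()
            raise ValueError(f"cannot unit-scale zero-SD species: {bad}")
        X = X / scales
    else:
        scales = pd.Series(1.0, index=matrix.columns)
    model = _SKPCA(n_components=ncomp, svd_solver="full")
    scores = model.fit_transform(X.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(ncomp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=matrix.columns,
                              columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
        means=means,
        scales=scales,
    )
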