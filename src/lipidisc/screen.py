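"""Plate-based siRNA screen scoring.

Readouts are per-well fractions of marker-positive (differentiating) cells.
Scoring proceeds in three steps:

1. robust standardization with the modified Z-score,
   ``z = 0.6745 · (x − median) / MAD``, computed within one normalization
   unit — by default one culture condition across its plates — which removes
   condition-level offsets and lets both conditions pool into one dataset;
2. per-plate fold changes of every well against the mean of the
   nontargeting-control wells on the same plate, computed per replicate and
   averaged for reporting;
3. volcano-style hit calling: a knockdown is an *inducer* when its fold
   change exceeds ``fc_high`` (default 2.5) with p < alpha, an *inhibitor*
   when the fold change is below ``fc_low`` (default 0.6) with p < alpha
   (Welch two-sample t of the target's pooled Z-values against the
   nontargeting wells of the same plates; both comparisons strict).

Involucrin-targeting wells (``positive_control``) gauge transfection
efficiency only: they are excluded from control means and from hit calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("lipidisc")

#: Iglewicz–Hoaglin consistency constant for the modified Z-score
MODIFIED_Z_CONSTANT = 0.6745

ROLES = ("test", "nontargeting", "no_siRNA", "positive_control")
CONTROL_TOKENS = {"nontargeting": "NTC", "no_siRNA": "noRNA",
                  "positive_control": "siINV"}


@dataclass(frozen=True)
class ScreenWell:
    """One well of a screening plate."""

    plate_id: str
    well: str                      # row letter + column number, e.g. "B07"
    target: str                    # gene symbol or control token
    role: str                      # test | nontargeting | no_siRNA | positive_control
    condition: str                 # growth | serum
    replicate: int
    readout: float                 # fraction of marker-positive cells

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not 0.0 <= self.readout <= 1.0:
            raise ValueError(
                f"readout {self.readout} outside [0, 1] "
                f"(plate {self.plate_id}, well {self.well})"
            )


@dataclass(frozen=True)
class HitCall:
    """Scored knockdown: pooled Z, fold change, p-value and the verdict."""

    target: str
    mean_z: float
    fold_change: float
    p_value: float
    call: str                      # inducer | inhibitor | none | uncalled


def wells_to_frame(wells: Iterable[ScreenWell]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in wells]).rename(
        columns={"plate_id": "plate"})


def read_screen_table(path) -> list[ScreenWell]:
    """Read a screen TSV (plate, well, target, role, condition, replicate, readout)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = ["plate", "well", "target", "role", "condition", "replicate", "readout"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        ScreenWell(str(r.plate), str(r.well), str(r.target), str(r.role),
                   str(r.condition), int(r.replicate), float(r.readout))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# modified Z-scores

def modified_zscore(
    values: Sequence[float], constant: float = MODIFIED_Z_CONSTANT
) -> np.ndarray:
    """Robust standardization: ``constant · (x − median) / MAD``.

    Requires ≥ 3 values and a positive median absolute deviation.  By
    construction the result has median 0 and median(|z|) = ``constant``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"modified Z-score needs ≥ 3 values, got {x.size}")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0:
        raise ValueError("MAD is zero: values are too concentrated to standardize")
    z = constant * (x - med) / mad
    assert abs(float(np.median(z))) < 1e-12
    assert abs(float(np.median(np.abs(z))) - constant) < 1e-12
    return z


def pool_conditions(
    wells: Iterable[ScreenWell],
    constant: float = MODIFIED_Z_CONSTANT,
    unit: Literal["condition", "plate"] = "condition",
) -> pd.DataFrame:
    """Modified Z within each normalization unit, concatenated across units.

    The default unit is a culture condition (all its plates and replicates
    together), so condition-level baseline offsets cancel and both arms of
    the screen pool into a single comparable dataset.  Returns the well
    table with a ``z`` column added.
    """
    df = wells_to_frame(wells)
    if df.empty:
        raise ValueError("no wells")
    key = "condition" if unit == "condition" else "plate"
    out = []
    for name, grp in df.groupby(key, sort=True):
        if len(grp) < 3:
            raise ValueError(f"normalization unit {name!r} has < 3 wells")
        grp = grp.copy()
        grp["z"] = modified_zscore(grp["readout"].to_numpy(), constant)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# fold changes

def plate_fold_change(df: pd.DataFrame) -> pd.DataFrame:
    """Per-well fold change against same-plate nontargeting control means.

    ``df`` is a well table (:func:`wells_to_frame` or :func:`pool_conditions`
    output).  Adds an ``fc`` column; raises when a plate lacks nontargeting
    wells or their mean readout is 0.
    """
    df = df.copy()
    fc = np.full(len(df), np.nan)
    for plate, grp in df.groupby("plate"):
        ctrl = grp.loc[grp["role"] == "nontargeting", "readout"]
        if ctrl.empty:
            raise ValueError(f"plate {plate!r} has no nontargeting wells")
        ref = float(ctrl.mean())
        if ref == 0:
            raise ValueError(f"plate {plate!r}: nontargeting control mean is 0")
        fc[grp.index] = grp["readout"] / ref
    df["fc"] = fc
    return df


# ---------------------------------------------------------------------------
# QC

def replicate_correlation(
    wells: Iterable[ScreenWell], constant: float = MODIFIED_Z_CONSTANT
) -> pd.Series:
    """Pearson r of each replicate's per-target Z against the replicate mean.

    Z-scores are pooled across conditions first; per target and replicate
    the well Z-values are averaged.  High r (the screen reported ~0.8)
    indicates reproducible knockdown effects.
    """
    pooled = pool_conditions(wells, constant)
    test = pooled[pooled["role"] == "test"]
    table = test.pivot_table(index="target", columns="replicate", values="z",
                             aggfunc="mean")
    if table.shape[1] < 2:
        raise ValueError("replicate correlation needs ≥ 2 replicates")
    mean = table.mean(axis=1)
    out = {}
    for rep in table.columns:
        col = table[rep]
        if col.std(ddof=1) == 0 or mean.std(ddof=1) == 0:
            raise ValueError(f"replicate {rep}: zero variance")
        out[rep] = float(np.corrcoef(col, mean)[0, 1])
    return pd.Series(out, name="pearson_r")


# ---------------------------------------------------------------------------
# hit calling

def call_hits(
    wells: Iterable[ScreenWell],
    fc_low: float = 0.6,
    fc_high: float = 2.5,
    alpha: float = 0.05,
    z_constant: float = MODIFIED_Z_CONSTANT,
) -> pd.DataFrame:
    """Score every test knockdown and call inducers/inhibitors.

    Per target: pooled mean modified Z, replicate-averaged same-plate fold
    change, and a two-sided Welch t of the target wells' Z-values against
    the Z-values of the nontargeting wells on the same plates.  Calls follow
    the strict volcano thresholds; targets with fewer than 2 usable wells
    are reported ``uncalled``.  The full table is returned regardless of
    call, sorted by target.
    """
    pooled = plate_fold_change(pool_conditions(wells, z_constant))
    test = pooled[pooled["role"] == "test"]
    ntc = pooled[pooled["role"] == "nontargeting"]
    rows = []
    for target, grp in test.groupby("target", sort=True):
        fc = float(grp["fc"].mean())
        mean_z = float(grp["z"].mean())
        ctrl = ntc[ntc["plate"].isin(grp["plate"].unique())]
        if len(grp) < 2 or len(ctrl) < 2:
            rows.append(HitCall(target, mean_z, fc, float("nan"), "uncalled"))
            continue
        p = float(stats.ttest_ind(grp["z"], ctrl["z"], equal_var=False).pvalue)
        if p < alpha and fc > fc_high:
            call = "inducer"
        elif p < alpha and fc < fc_low:
            call = "inhibitor"
        else:
            call = "none"
        rows.append(HitCall(target, mean_z, fc, p, call))
    return pd.DataFrame([h.__dict__ for h in rows])
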