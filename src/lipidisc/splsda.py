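"""Sparse partial least squares discriminant analysis (sPLS-DA).

A NIPALS-style power iteration on the cross-covariance between the predictor
matrix X (samples × species) and a one-hot class indicator Y, with per
component *hard* selection of a fixed number ``keepX`` of predictors: at
every iteration the X-weight vector is thresholded to its keepX largest
absolute entries, renormalized, and both X and Y are deflated on the X-score
(regression mode) before the next component is extracted.

The sign of any latent component is arbitrary; :func:`orient_component`
fixes it so a designated reference class scores non-negatively, which makes
signed loading thresholds reproducible across implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lipidisc")


@dataclass(frozen=True)
class ClassDesign:
    """Per-sample class labels and their one-hot indicator matrix."""

    labels: tuple[str, ...]
    classes: tuple[str, ...]       # lexicographic order
    dummy: np.ndarray              # (n_samples, n_classes), rows sum to 1

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("discriminant analysis requires ≥ 2 classes")
        if self.dummy.shape != (len(self.labels), len(self.classes)):
            raise ValueError("dummy matrix shape mismatch")


def dummy_encode(labels: Sequence[str]) -> ClassDesign:
    """One-hot encode class labels; classes ordered lexicographically."""
    labels = tuple(str(x) for x in labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError(f"need ≥ 2 distinct class labels, got {set(labels)}")
    col = {c: k for k, c in enumerate(classes)}
    dummy = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        dummy[i, col[lab]] = 1.0
    return ClassDesign(labels, classes, dummy)


@dataclass
class SPLSDAModel:
    """Fitted sparse PLS-DA model.

    ``x_weights`` are the sparse, unit-norm selection vectors (exactly
    ``min(keepX, p)`` nonzeros per component) — these are the "loadings"
    that the discriminant thresholds operate on.  ``x_loadings`` are the
    regression loadings Xᵀt/(tᵀt) used for deflation.
    """

    ncomp: int
    keepX: tuple[int, ...]
    classes: tuple[str, ...]
    labels: tuple[str, ...]
    x_weights: pd.DataFrame       # species × ncomp
    x_loadings: pd.DataFrame      # species × ncomp
    y_weights: pd.DataFrame       # classes × ncomp
    scores: pd.DataFrame          # samples × ncomp
    means: pd.Series
    scales: pd.Series
    iterations: list[int]
    deltas: list[float]
    converged: list[bool]

    def component_name(self, comp: int) -> str:
        if not 1 <= comp <= self.ncomp:
            raise ValueError(f"component {comp} out of range 1..{self.ncomp}")
        return f"comp{comp}"


def _hard_threshold(u: np.ndarray, keep: int) -> np.ndarray:
    """Zero all but the ``keep`` largest |entries|; ties keep smaller index."""
    p = u.size
    if keep >= p:
        return u.copy()
    order = np.lexsort((np.arange(p), -np.abs(u)))
    out = np.zeros_like(u)
    sel = order[:keep]
    out[sel] = u[sel]
    return out


def fit_splsda(
    X: pd.DataFrame,
    design: ClassDesign | Sequence[str],
    ncomp: int = 3,
    keepX: Sequence[int] | int = 250,
    scale: bool = True,
    threshold_mode: str = "hard",
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SPLSDAModel:
    """Fit sparse PLS-DA on a samples × species table.

    Parameters
    ----------
    X
        Predictor table (mol% or Z-scores), near-zero-variance species
        already removed.
    design
        Class labels (one per sample) or a pre-built :class:`ClassDesign`.
    ncomp, keepX
        Number of latent components and per-component number of species to
        retain; a scalar keepX is broadcast.  keepX larger than the number
        of species is clamped with a warning.
    scale
        Unit-variance scale the X columns (sample SD) in addition to
        centering; the class indicator is centered only.
    threshold_mode
        ``"hard"`` (pure selection, default) or ``"soft"`` (survivors are
        shrunk by the largest discarded magnitude before renormalization).
    """
    if not isinstance(design, ClassDesign):
        design = dummy_encode(design)
    n, p = X.shape
    if n < 3:
        raise ValueError("sPLS-DA requires at least 3 samples")
    if len(design.labels) != n:
        raise ValueError("label count does not match number of samples")
    if ncomp < 1:
        raise ValueError("ncomp must be ≥ 1")
    if ncomp > min(n - 1, p):
        raise ValueError(f"ncomp {ncomp} exceeds min(n-1, p) = {min(n - 1, p)}")
    if np.isscalar(keepX):
        keepX = [int(keepX)] * ncomp
    keepX = [int(k) for k in keepX]
    if len(keepX) != ncomp:
        raise ValueError(f"keepX has {len(keepX)} entries for ncomp={ncomp}")
    if any(k < 1 for k in keepX):
        raise ValueError("keepX entries must be ≥ 1")
    clamped = [min(k, p) for k in keepX]
    if clamped != keepX:
        logger.warning("keepX %s clamped to %d species", keepX, p)
    keepX = clamped
    if threshold_mode not in ("hard", "soft"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    means = X.mean(axis=0)
    if scale:
        scales = X.std(axis=0, ddof=1)
        if (scales == 0).any():
            bad = scales[scales == 0].index.tolist()
            raise ValueError(
                f"zero-variance species must be removed before fitting: {bad[:5]}"
            )
    else:
        scales = pd.Series(1.0, index=X.columns)
    Xc = ((X - means) / scales).to_numpy()
    Y = design.dummy - design.dummy.mean(axis=0)

    x_weights = np.zeros((p, ncomp))
    x_loadings = np.zeros((p, ncomp))
    y_weights = np.zeros((Y.shape[1], ncomp))
    scores = np.zeros((n, ncomp))
    iterations, deltas, converged = [], [], []

    for c in range(ncomp):
        M = Y.T @ Xc  # q × p cross-covariance
        # deterministic init: leading left singular vector of YᵀX
        U, _, _ = np.linalg.svd(M, full_matrices=False)
        v = U[:, 0]
        u_old = np.zeros(p)
        it = 0
        delta = np.inf
        for it in range(1, max_iter + 1):
            u = Xc.T @ (Y @ v)
            if threshold_mode == "soft" and keepX[c] < p:
                lam = np.sort(np.abs(u))[::-1][keepX[c]]
                u = np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)
                u = _hard_threshold(u, keepX[c])  # resolve ties at the cut
            else:
                u = _hard_threshold(u, keepX[c])
            norm = np.linalg.norm(u)
            if norm == 0:
                raise RuntimeError(f"component {c + 1}: weight vector collapsed to 0")
            u = u / norm
            v = Y.T @ (Xc @ u)
            v = v / np.linalg.norm(v)
            delta = float(np.linalg.norm(u - u_old))
            if delta < tol:
                break
            u_old = u
        ok = delta < tol
        if not ok:
            logger.warning(
                "component %d did not converge after %d iterations (delta=%.2e); "
                "keeping last iterate", c + 1, max_iter, delta,
            )
        t = Xc @ u
        tt = float(t @ t)
        load = Xc.T @ t / tt
        Xc = Xc - np.outer(t, load)
        Y = Y - np.outer(t, (Y.T @ t) / tt)
        x_weights[:, c] = u
        x_loadings[:, c] = load
        y_weights[:, c] = v
        scores[:, c] = t
        iterations.append(it)
        deltas.append(delta)
        converged.append(ok)

    comp_names = [f"comp{i + 1}" for i in range(ncomp)]
    return SPLSDAModel(
        ncomp=ncomp,
        keepX=tuple(keepX),
        classes=design.classes,
        labels=design.labels,
        x_weights=pd.DataFrame(x_weights, index=X.columns, columns=comp_names),
        x_loadings=pd.DataFrame(x_loadings, index=X.columns, columns=comp_names),
        y_weights=pd.DataFrame(y_weights, index=list(design.classes),
                               columns=comp_names),
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        means=means,
        scales=scales,
        iterations=iterations,
        deltas=deltas,
        converged=converged,
    )


def orient_component(
    model: SPLSDAModel, comp: int, reference_class: str
) -> SPLSDAModel:
    """Flip a component's sign so the reference class scores ≥ 0 on average.

    Weights, loadings, scores and Y-weights flip together; a zero mean score
    leaves the component unchanged.  Idempotent.
    """
    name = model.component_name(comp)
    if reference_class not in model.classes:
        raise ValueError(f"reference class {reference_class!r} not in design")
    mask = np.array([lab == reference_class for lab in model.labels])
    mean_score = float(model.scores.loc[mask, name].mean())
    if mean_score >= 0:
        return model
    new = replace(
        model,
        x_weights=model.x_weights.copy(),
        x_loadings=model.x_loadings.copy(),
        y_weights=model.y_weights.copy(),
        scores=model.scores.copy(),
    )
    for frame in (new.x_weights, new.x_loadings, new.y_weights, new.scores):
        frame[name] = -frame[name]
    return new


def component_loadings(
    model: SPLSDAModel, comp: int, top: int | None = None
) -> tuple[pd.Series, pd.Series]:
    """Sparse weight vector of one component on the original species index.

    Returns ``(full, top_k)``: the full vector (zeros for unselected
    species) and the ``top`` entries ranked by |loading| descending (all
    nonzero entries when ``top`` is None).
    """
    name = model.component_name(comp)
    full = model.x_weights[name].copy()
    nz = full[full != 0]
    ranked = nz.reindex(nz.abs().sort_values(ascending=False, kind="stable").index)
    if top is not None:
        ranked = ranked.iloc[:top]
    return full, ranked
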