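"""End-to-end pipeline runs driven by a single validated configuration.

``run_pipeline`` wires the stages together — simulate (or ingest), mol%
normalization, class composition, Z-scores, clustering, PCA, sPLS-DA,
discriminant extraction, intersections, screen scoring — writing every
stage artifact as TSV plus one machine-readable ``summary.json``.  For
simulated inputs the configuration hash fully determines every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import (
    class_composition,
    hierarchical_cluster,
    normalize_molpct,
    pca,
    read_lipidomics_table,
    remove_near_zero_variance,
    zscore_by_species,
)
from .discriminants import (
    intersect_sets,
    knockdown_discriminants,
    max_fold_change_table,
    suspension_discriminants,
)
from .screen import call_hits, read_screen_table, replicate_correlation, wells_to_frame
from .simulate import simulate_knockdown, simulate_screen, simulate_suspension

logger = logging.getLogger("lipidisc")


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    # optional real inputs (long-layout lipidomics TSVs and a screen TSV)
    suspension_path: str | None = None
    knockdown_48_path: str | None = None
    knockdown_72_path: str | None = None
    screen_path: str | None = None
    # sPLS-DA
    ncomp: int = 3
    keepX: tuple[int, ...] = (250, 250, 250)
    scale: bool = True
    # discriminant extraction
    loading_threshold: float = 0.01
    # screen scoring
    fc_low: float = 0.6
    fc_high: float = 2.5
    alpha: float = 0.05
    z_constant: float = 0.6745

    def __post_init__(self) -> None:
        self.keepX = tuple(int(k) for k in self.keepX)
        if len(self.keepX) != self.ncomp:
            raise ValueError(
                f"keepX has {len(self.keepX)} entries but ncomp={self.ncomp}"
            )
        for name in ("loading_threshold", "fc_low", "fc_high", "alpha", "z_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.simulate and self.suspension_path is None:
            raise ValueError("either simulate=True or input paths are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the summary (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    summary: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
    }
    try:
        stage = "inputs"
        if config.simulate:
            suspension, susp_truth = simulate_suspension(seed=config.seed)
            kd, kd_truth = simulate_knockdown(seed=config.seed)
            ds48, ds72 = kd[48.0], kd[72.0]
            wells, screen_truth = simulate_screen(seed=config.seed)
            (out / "truth.json").write_text(json.dumps({
                "suspension": susp_truth.to_dict(),
                "knockdown": kd_truth.to_dict(),
                "screen": screen_truth.to_dict(),
            }, indent=2))
        else:
            suspension = read_lipidomics_table(config.suspension_path)
            ds48 = read_lipidomics_table(config.knockdown_48_path)
            ds72 = read_lipidomics_table(config.knockdown_72_path)
            wells = (read_screen_table(config.screen_path)
                     if config.screen_path else None)

        stage = "normalize"
        molpct = normalize_molpct(suspension)
        _write(molpct, out / "suspension_molpct.tsv")

        stage = "classcomp"
        _write(class_composition(molpct), out / "suspension_class_composition.tsv")

        stage = "zscore"
        z = zscore_by_species(molpct)
        _write(z, out / "suspension_zscores.tsv")

        stage = "cluster"
        link = hierarchical_cluster(z, axis="samples")
        _write(pd.DataFrame(link.linkage,
                            columns=["child_a", "child_b", "height", "size"]),
               out / "suspension_linkage.tsv", index=False)
        (out / "suspension_leaf_order.txt").write_text(
            "\n".join(link.labels[i] for i in link.leaf_order) + "\n")

        stage = "pca"
        filtered, nzv = remove_near_zero_variance(molpct)
        fit = pca(filtered, ncomp=min(config.ncomp, filtered.shape[0] - 1),
                  scale=config.scale)
        _write(fit.scores, out / "suspension_pca_scores.tsv")
        _write(fit.loadings, out / "suspension_pca_loadings.tsv")

        stage = "splsda+discriminants (suspension)"
        susp_set, susp_model = suspension_discriminants(
            suspension, ncomp=config.ncomp, keepX=max(config.keepX),
            loading_threshold=config.loading_threshold)
        _write(susp_model.scores, out / "suspension_splsda_scores.tsv")
        _write(susp_model.x_weights, out / "suspension_splsda_loadings.tsv")
        _write(susp_set.to_frame(), out / "suspension_discriminants.tsv",
               index=False)

        stage = "discriminants (knockdown)"
        kd_sets = {}
        for target in ("siELOVL1", "siSLC27A1"):
            dset, _models = knockdown_discriminants(
                ds48, ds72, target, ncomp=config.ncomp, keepX=max(config.keepX),
                loading_threshold=config.loading_threshold)
            kd_sets[target] = dset
            _write(dset.to_frame(), out / f"{target}_discriminants.tsv",
                   index=False)
            _write(max_fold_change_table(dset),
                   out / f"{target}_max_fold_change.tsv", index=False)

        stage = "intersection"
        inter = {}
        for target, dset in kd_sets.items():
            ix = intersect_sets(susp_set, dset)
            inter[target] = ix
            _write(ix.to_frame(), out / f"intersection_{target}.tsv", index=False)

        summary["set_sizes"] = {
            "suspension": len(susp_set),
            "siELOVL1": len(kd_sets["siELOVL1"]),
            "siSLC27A1": len(kd_sets["siSLC27A1"]),
            "intersection_siELOVL1": len(inter["siELOVL1"]),
            "intersection_siSLC27A1": len(inter["siSLC27A1"]),
        }
        summary["nzv_removed"] = len(nzv.removed)
        summary["explained_variance_ratio"] = [
            float(x) for x in fit.explained_variance_ratio]

        if wells is not None:
            stage = "screen"
            _write(wells_to_frame(wells), out / "screen_wells.tsv", index=False)
            hits = call_hits(wells, fc_low=config.fc_low, fc_high=config.fc_high,
                             alpha=config.alpha, z_constant=config.z_constant)
            _write(hits, out / "screen_hits.tsv", index=False)
            corr = replicate_correlation(wells, config.z_constant)
            _write(corr.to_frame(), out / "screen_replicate_correlation.tsv")
            called = hits[hits["call"].isin(["inducer", "inhibitor"])]
            summary["screen"] = {
                "n_targets": int(hits.shape[0]),
                "hits": {row.target: row.call for row in called.itertuples()},
                "replicate_correlation": {str(k): float(v)
                                          for k, v in corr.items()},
            }
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
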