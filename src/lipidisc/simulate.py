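"""Synthetic lipidomes, time-course designs and screens with known truth.

The generators emulate the *statistical shape* of the study's three data
types — they make every pipeline stage testable with a known answer, without
claiming fidelity to any real lipidome's absolute values:

* a class-structured lipidome: per-class baseline mol% shares (PC-dominant,
  minor Cer/HexCer, as in cultured mammalian cells) split across species by
  a lognormal abundance law;
* the suspension-differentiation design (0/4/8/12/24 h × control/PKCi,
  duplicate cultures) with three planted signatures: an adherent signature
  (species elevated only at 0 h, mimicking the large lipidomic shift that
  detachment causes), transient commitment markers (elevated at 4–8 h in
  control only) and differentiated markers (ramping up at 12–24 h in
  control only, blocked under PKCi);
* the knockdown design ({siScramble, siELOVL1, siSLC27A1} × {24, 48, 72} h,
  triplicate) with planted target-specific enrichment from 48 h, including
  control-undetectable species that exercise the ``Accumulated`` sentinel;
* 96-well screening plates (90 test wells + 2 nontargeting, 2 no-siRNA and
  2 involucrin-positive control wells each, quadruplicate, two culture
  conditions) with planted inducer/inhibitor effects, condition-level
  baseline shifts and per-plate offsets.

All randomness flows from one integer seed; independent sub-streams are
derived by stable hashing of entity names, so regenerating with the same
seed is byte-identical and adding entities does not perturb existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from math import ceil
from typing import Sequence

import numpy as np

from .core import LipidomicsDataset, SampleDesign
from .nomenclature import (
    CLASS_CHAIN_COUNT,
    ChainDescriptor,
    LipidSpecies,
    SPHINGOLIPID_CLASSES,
)
from .screen import ScreenWell


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent deterministic stream for one named entity."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# lipidome profile

@dataclass
class LipidomeProfile:
    """Baseline class composition and noise law of a synthetic lipidome.

    ``class_shares`` (normalized to sum to 1) set the baseline mol% of each
    class; ``class_counts`` how many species represent it.  Species within
    a class split the class share lognormally (``species_sigma`` on the log
    scale, spanning roughly two orders of magnitude at the default 0.8).
    ``replicate_sigma`` is the per-(sample, species) multiplicative
    measurement/culture noise on the log scale (0.04 ≈ 4% CV, the scale of
    technical variation of direct-infusion MS on abundant species,
    calibrated so the four differentiation classes separate as cleanly in
    latent space as the study's score plots show); per-sample total
    amounts jitter by ±``total_jitter`` around ``total_pmol``.
    """

    class_counts: dict[str, int] = field(default_factory=lambda: {
        "PC": 60, "PC O-": 15, "PE": 38, "PE O-": 20, "PS": 25, "PI": 20,
        "PA": 10, "PG": 8, "LPC": 6, "LPE": 6, "Cer": 15, "HexCer": 10,
        "SM": 18, "DAG": 12, "TAG": 28, "CE": 8, "Chol": 1,
    })
    class_shares: dict[str, float] = field(default_factory=lambda: {
        "PC": 0.28, "PC O-": 0.04, "PE": 0.11, "PE O-": 0.05, "PS": 0.07,
        "PI": 0.06, "PA": 0.015, "PG": 0.01, "LPC": 0.005, "LPE": 0.005,
        "Cer": 0.02, "HexCer": 0.01, "SM": 0.06, "DAG": 0.03, "TAG": 0.12,
        "CE": 0.04, "Chol": 0.07,
    })
    species_sigma: float = 0.8
    replicate_sigma: float = 0.04
    total_pmol: float = 1000.0
    total_jitter: float = 0.30

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("species counts must be ≥ 0")
        if self.species_sigma <= 0 or self.replicate_sigma <= 0:
            raise ValueError("sigmas must be > 0")
        total = sum(self.class_shares.get(k, 0.0)
                    for k, n in self.class_counts.items() if n > 0)
        if total <= 0:
            raise ValueError("class shares must sum to > 0")
        self.class_shares = {
            k: self.class_shares.get(k, 0.0) / total
            for k in self.class_counts
        }

    @property
    def n_species(self) -> int:
        return sum(self.class_counts.values())


def _draw_chain(rng, lo=14, hi=24, max_unsat=4, hydrox=0) -> ChainDescriptor:
    c = int(rng.integers(lo, hi + 1))
    u = int(rng.integers(0, min(max_unsat, c - 1) + 1))
    return ChainDescriptor(c, u, hydrox)


def _draw_species(rng, lipid_class: str) -> LipidSpecies:
    ether = lipid_class.endswith("O-")
    nchain = CLASS_CHAIN_COUNT[lipid_class]
    if lipid_class in SPHINGOLIPID_CLASSES:
        fa = int(rng.integers(12, 27))  # fatty-acid moiety C12–C26
        unsat = 1 + int(rng.integers(0, 3))
        chains = (ChainDescriptor(18 + fa, unsat, 2),)
    elif lipid_class == "CE":
        chains = (_draw_chain(rng, 14, 22, 4),)
    elif lipid_class == "Chol":
        chains = ()
    elif nchain == 1:  # lyso classes
        chains = (_draw_chain(rng),)
    else:
        drawn = sorted(
            (_draw_chain(rng, 14, 24 if nchain == 2 else 22,
                         4 if nchain == 2 else 3) for _ in range(nchain)),
        )
        chains = tuple(drawn)
    return LipidSpecies(lipid_class, chains, ether)


def random_species(
    profile: LipidomeProfile, seed: int, n_per_class: dict[str, int] | None = None
) -> list[LipidSpecies]:
    """Draw a unique, grammar-valid species panel for the profile.

    Chain lengths cover the physiological 14–24 carbon fatty-acyl range with
    up to four unsaturations (sphingolipid totals include the d18:1 base).
    Deterministic given the seed.
    """
    counts = dict(profile.class_counts if n_per_class is None else n_per_class)
    out: list[LipidSpecies] = []
    for lipid_class in sorted(counts):
        n = counts[lipid_class]
        if n == 0:
            continue
        rng = _rng(seed, f"species/{lipid_class}")
        seen: set[LipidSpecies] = set()
        tries = 0
        while len(seen) < n:
            tries += 1
            if tries > 100 * n + 1000:
                raise RuntimeError(
                    f"cannot draw {n} unique {lipid_class} species"
                )
            seen.add(_draw_species(rng, lipid_class))
        out.extend(sorted(seen, key=lambda s: s.canonical()))
    return out


def _baseline_shares(
    profile: LipidomeProfile, species: Sequence[LipidSpecies], seed: int
) -> np.ndarray:
    """Per-species baseline fraction of total lipid (sums to 1)."""
    shares = np.zeros(len(species))
    by_class: dict[str, list[int]] = {}
    for i, sp in enumerate(species):
        by_class.setdefault(sp.lipid_class, []).append(i)
    for lipid_class, idx in by_class.items():
        rng = _rng(seed, f"baseline/{lipid_class}")
        raw = np.exp(rng.normal(0.0, profile.species_sigma, size=len(idx)))
        shares[idx] = profile.class_shares[lipid_class] * raw / raw.sum()
    return shares / shares.sum()


# ---------------------------------------------------------------------------
# truth bookkeeping

@dataclass(frozen=True)
class PlantedSpeciesEffect:
    species: str                 # canonical annotation
    group: str                   # class label or treatment the effect targets
    multiplier: float
    timepoints: tuple[float, ...]
    control_zero: bool = False   # exercises the Accumulated sentinel


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic dataset."""

    seed: int
    planted_species: list[PlantedSpeciesEffect] = field(default_factory=list)
    planted_hits: list[tuple[str, str, float]] = field(default_factory=list)

    def species_for(self, group: str) -> set[str]:
        return {p.species for p in self.planted_species if p.group == group}

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# suspension time course

@dataclass
class SuspensionEffects:
    """Planted signatures of the suspension-differentiation simulation.

    Defaults mirror the study conditions the pipeline must resolve: 20
    differentiated markers at 3× (ramping in at 12 h, full at 24 h), a dozen
    transient commitment markers, and a strong adherent signature so the
    detachment axis dominates the first latent component as it does in the
    real data.  Set all counts to 0 for a null simulation.
    """

    n_adherent: int = 50
    adherent_multiplier: float = 3.0
    n_commitment: int = 15
    commitment_multiplier: float = 3.0
    n_differentiated: int = 20
    differentiated_multiplier: float = 3.0


def _suspension_designs(n_rep: int) -> list[SampleDesign]:
    designs = []
    for rep in range(1, n_rep + 1):
        designs.append(SampleDesign(f"susp_0h_control_r{rep}", "suspension",
                                    0.0, "control", rep))
    for tp in (4.0, 8.0, 12.0, 24.0):
        for treatment in ("control", "PKCi"):
            for rep in range(1, n_rep + 1):
                designs.append(SampleDesign(
                    f"susp_{int(tp)}h_{treatment}_r{rep}", "suspension",
                    tp, treatment, rep))
    return designs


def simulate_suspension(
    profile: LipidomeProfile | None = None,
    effects: SuspensionEffects | None = None,
    n_rep: int = 2,
    seed: int = 0,
) -> tuple[LipidomicsDataset, SimulationTruth]:
    """Simulate the suspension-differentiation lipidomics time course.

    Duplicate cultures at 0/4/8/12/24 h, control and PKCi arms; the PKCi arm
    receives no planted differentiation effects (inhibition blocks them).
    Returns the pmol dataset (per-sample totals jittered ±30%) and the truth.
    """
    profile = profile or LipidomeProfile()
    effects = effects if effects is not None else SuspensionEffects()
    species = random_species(profile, seed)
    shares = _baseline_shares(profile, species, seed)
    designs = _suspension_designs(n_rep)
    n, p = len(designs), len(species)

    pick_rng = _rng(seed, "suspension/planted")
    n_planted = effects.n_adherent + effects.n_commitment + effects.n_differentiated
    if n_planted > p:
        raise ValueError("more planted species than species in the panel")
    chosen = pick_rng.choice(p, size=n_planted, replace=False)
    adherent_idx = chosen[: effects.n_adherent]
    commitment_idx = chosen[effects.n_adherent:
                            effects.n_adherent + effects.n_commitment]
    differentiated_idx = chosen[effects.n_adherent + effects.n_commitment:]

    # per-sample multiplier matrix
    mult = np.ones((n, p))
    ramp = {12.0: 0.75, 24.0: 1.0}
    for si, d in enumerate(designs):
        tp, tr = d.timepoint, d.treatment
        if tp == 0.0:
            mult[si, adherent_idx] = effects.adherent_multiplier
        if tr == "control" and tp in (4.0, 8.0):
            mult[si, commitment_idx] = effects.commitment_multiplier
        if tr == "control" and tp in ramp:
            mult[si, differentiated_idx] = (
                effects.differentiated_multiplier ** ramp[tp]
            )

    noise_rng = _rng(seed, "suspension/noise")
    noise = np.exp(noise_rng.normal(0.0, profile.replicate_sigma, size=(n, p)))
    total_rng = _rng(seed, "suspension/totals")
    totals = profile.total_pmol * total_rng.uniform(
        1 - profile.total_jitter, 1 + profile.total_jitter, size=n)
    abundance = totals[:, None] * shares[None, :] * mult * noise

    truth = SimulationTruth(seed=seed)
    names = [sp.canonical() for sp in species]
    for idx, group, m, tps in (
        (adherent_idx, "adherent", effects.adherent_multiplier, (0.0,)),
        (commitment_idx, "commitment", effects.commitment_multiplier, (4.0, 8.0)),
        (differentiated_idx, "differentiated",
         effects.differentiated_multiplier, (12.0, 24.0)),
    ):
        for j in idx:
            truth.planted_species.append(
                PlantedSpeciesEffect(names[j], group, m, tps))
    return LipidomicsDataset(designs, species, abundance), truth


# ---------------------------------------------------------------------------
# knockdown time course

KNOCKDOWN_TREATMENTS = ("siScramble", "siELOVL1", "siSLC27A1")
KNOCKDOWN_TIMEPOINTS = (24.0, 48.0, 72.0)


@dataclass
class KnockdownEffects:
    """Planted signatures of the knockdown time-course simulation.

    The defaults plant a strong siELOVL1 lipid shift (20 species at 3× from
    48 h, plus 2 species undetectable in the control — the ``Accumulated``
    case) and a milder siSLC27A1 shift, matching the study's observation
    that the ELOVL1 knockdown remodels the lipidome much more than the
    SLC27A1 knockdown.  Set counts to 0 for a null simulation.
    """

    n_elovl1: int = 20
    elovl1_multiplier: float = 3.0
    elovl1_timepoints: tuple[float, ...] = (48.0, 72.0)
    n_accumulated: int = 2
    n_slc27a1: int = 12
    slc27a1_multiplier: float = 2.5
    slc27a1_timepoints: tuple[float, ...] = (48.0, 72.0)


def simulate_knockdown(
    profile: LipidomeProfile | None = None,
    effects: KnockdownEffects | None = None,
    n_rep: int = 3,
    seed: int = 0,
) -> tuple[dict[float, LipidomicsDataset], SimulationTruth]:
    """Simulate the siRNA knockdown lipidomics time course.

    Triplicate independent transfections of siScramble / siELOVL1 /
    siSLC27A1 collected at 24, 48 and 72 h; returns one dataset per
    timepoint (they share the species panel) plus the truth.  Species
    flagged ``control_zero`` have abundance exactly 0 in siScramble.
    """
    profile = profile or LipidomeProfile()
    effects = effects if effects is not None else KnockdownEffects()
    species = random_species(profile, seed)
    shares = _baseline_shares(profile, species, seed)
    names = [sp.canonical() for sp in species]
    p = len(species)

    pick_rng = _rng(seed, "knockdown/planted")
    n_planted = effects.n_elovl1 + effects.n_accumulated + effects.n_slc27a1
    if n_planted > p:
        raise ValueError("more planted species than species in the panel")
    chosen = pick_rng.choice(p, size=n_planted, replace=False)
    elovl1_idx = chosen[: effects.n_elovl1]
    accum_idx = chosen[effects.n_elovl1: effects.n_elovl1 + effects.n_accumulated]
    slc27a1_idx = chosen[effects.n_elovl1 + effects.n_accumulated:]

    truth = SimulationTruth(seed=seed)
    for j in elovl1_idx:
        truth.planted_species.append(PlantedSpeciesEffect(
            names[j], "siELOVL1", effects.elovl1_multiplier,
            effects.elovl1_timepoints))
    for j in accum_idx:
        truth.planted_species.append(PlantedSpeciesEffect(
            names[j], "siELOVL1", effects.elovl1_multiplier,
            effects.elovl1_timepoints, control_zero=True))
    for j in slc27a1_idx:
        truth.planted_species.append(PlantedSpeciesEffect(
            names[j], "siSLC27A1", effects.slc27a1_multiplier,
            effects.slc27a1_timepoints))

    datasets: dict[float, LipidomicsDataset] = {}
    for tp in KNOCKDOWN_TIMEPOINTS:
        designs = [
            SampleDesign(f"kd_{int(tp)}h_{tr}_r{rep}", "knockdown", tp, tr, rep)
            for tr in KNOCKDOWN_TREATMENTS for rep in range(1, n_rep + 1)
        ]
        n = len(designs)
        mult = np.ones((n, p))
        zero = np.zeros((n, p), dtype=bool)
        for si, d in enumerate(designs):
            if d.treatment == "siELOVL1" and tp in effects.elovl1_timepoints:
                mult[si, elovl1_idx] = effects.elovl1_multiplier
                mult[si, accum_idx] = effects.elovl1_multiplier
            if d.treatment == "siSLC27A1" and tp in effects.slc27a1_timepoints:
                mult[si, slc27a1_idx] = effects.slc27a1_multiplier
            if d.treatment != "siELOVL1" or tp not in effects.elovl1_timepoints:
                zero[si, accum_idx] = True  # undetectable outside the knockdown
        noise_rng = _rng(seed, f"knockdown/noise/{int(tp)}")
        noise = np.exp(noise_rng.normal(0.0, profile.replicate_sigma, size=(n, p)))
        total_rng = _rng(seed, f"knockdown/totals/{int(tp)}")
        totals = profile.total_pmol * total_rng.uniform(
            1 - profile.total_jitter, 1 + profile.total_jitter, size=n)
        abundance = totals[:, None] * shares[None, :] * mult * noise
        abundance[zero] = 0.0
        datasets[tp] = LipidomicsDataset(designs, species, abundance)
    return datasets, truth


# ---------------------------------------------------------------------------
# siRNA screen

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12
TEST_WELLS_PER_PLATE = 90  # 96 minus 2 nontargeting + 2 no-siRNA + 2 positive


@dataclass
class ScreenSettings:
    """Baselines and noise of the synthetic screen.

    Baseline differentiating-cell fractions: ~5% in growth medium and ~15%
    under serum stimulation (the condition-level shift the modified Z-score
    must remove); per-well noise is lognormal with SD 15% of the level;
    plates carry small random offsets; the involucrin positive-control wells
    knock the readout down to 20% of baseline.
    """

    baseline: dict[str, float] = field(default_factory=lambda: {
        "growth": 0.05, "serum": 0.15})
    noise_sigma: float = 0.15
    plate_sigma: float = 0.05
    positive_control_multiplier: float = 0.2


def default_planted_hits(
    n_targets: int = 258, seed: int = 0,
    n_down: int = 4, down_multiplier: float = 0.4,
    n_up: int = 6, up_multiplier: float = 3.5,
) -> list[tuple[str, str, float]]:
    """The study-shaped hit panel: 4 differentiation inhibitors, 6 inducers."""
    rng = _rng(seed, "screen/hits")
    idx = rng.choice(n_targets, size=n_down + n_up, replace=False)
    hits = []
    for k, i in enumerate(idx):
        gene = f"GENE{i + 1:03d}"
        if k < n_down:
            hits.append((gene, "down", down_multiplier))
        else:
            hits.append((gene, "up", up_multiplier))
    return hits


def simulate_screen(
    n_targets: int = 258,
    planted_hits: list[tuple[str, str, float]] | None = None,
    n_rep: int = 4,
    settings: ScreenSettings | None = None,
    conditions: tuple[str, ...] = ("growth", "serum"),
    seed: int = 0,
) -> tuple[list[ScreenWell], SimulationTruth]:
    """Simulate the quadruplicate two-condition siRNA screen.

    Targets fill 96-well plates at 90 per plate; every plate carries two
    nontargeting, two no-siRNA and two involucrin positive-control wells.
    Readout = condition baseline × plate offset × planted multiplier ×
    lognormal noise, clipped to [0, 1].
    """
    settings = settings or ScreenSettings()
    if planted_hits is None:
        planted_hits = default_planted_hits(n_targets, seed)
    targets = [f"GENE{i + 1:03d}" for i in range(n_targets)]
    mult = {g: m for g, _, m in planted_hits}
    unknown = sorted(set(mult) - set(targets))
    if unknown:
        raise ValueError(f"planted hits not in target panel: {unknown}")

    n_plates = ceil(n_targets / TEST_WELLS_PER_PLATE)
    well_names = [f"{r}{c:02d}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]
    wells: list[ScreenWell] = []
    for condition in conditions:
        base = settings.baseline[condition]
        for rep in range(1, n_rep + 1):
            for plate_num in range(n_plates):
                plate_id = f"{condition}-r{rep}-p{plate_num + 1}"
                offset_rng = _rng(seed, f"screen/offset/{plate_id}")
                offset = float(np.exp(offset_rng.normal(0.0, settings.plate_sigma)))
                noise_rng = _rng(seed, f"screen/noise/{plate_id}")
                plate_targets = targets[plate_num * TEST_WELLS_PER_PLATE:
                                        (plate_num + 1) * TEST_WELLS_PER_PLATE]
                layout: list[tuple[str, str, float]] = [
                    (g, "test", mult.get(g, 1.0)) for g in plate_targets
                ]
                layout += [("NTC", "nontargeting", 1.0)] * 2
                layout += [("noRNA", "no_siRNA", 1.0)] * 2
                layout += [("siINV", "positive_control",
                            settings.positive_control_multiplier)] * 2
                for pos, (gene, role, m) in enumerate(layout):
                    noise = float(np.exp(noise_rng.normal(0.0, settings.noise_sigma)))
                    readout = float(np.clip(base * offset * m * noise, 0.0, 1.0))
                    wells.append(ScreenWell(
                        plate_id, well_names[pos], gene, role, condition,
                        rep, readout))
    truth = SimulationTruth(seed=seed, planted_hits=list(planted_hits))
    return wells, truth
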