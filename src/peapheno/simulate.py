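"""Simulation of trait tables under the additive two-way random model.

Each record of a balanced genotype x condition experiment with r replicates
is generated as

    y_ijk = mu + G_i + C_j + (GC)_ij + e_ijk

with independent zero-mean normal effects at the stated variances. This is
the generative counterpart of the variance-component estimator in
:mod:`peapheno.stats`: simulating at known (sigma2_G, sigma2_C, sigma2_GC,
sigma2_E) and estimating them back is the core parameter-recovery check.

The condition term can alternatively be a pair of fixed offsets, which is
the right framing for sensitivity-index work where drought shifts each
trait mean by a designed amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from peapheno.reference import SPECIES_GROUPS, TRAITS, table1_means

CONDITIONS = ("control", "drought")


@dataclass(frozen=True)
class SimulationParams:
    """Design sizes and variance components of one simulated trait.

    ``condition_offsets`` (one per condition), when given, replaces the
    random condition effect: sigma2_C is then ignored.
    """

    n_accessions: int = 180
    n_conditions: int = 2
    n_reps: int = 3
    grand_mean: float = 0.0
    sigma2_G: float = 1.0
    sigma2_C: float = 0.0
    sigma2_GC: float = 0.0
    sigma2_E: float = 1.0
    condition_offsets: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_accessions, self.n_conditions, self.n_reps) < 1:
            raise ValueError("all design counts must be >= 1")
        if min(self.sigma2_G, self.sigma2_C, self.sigma2_GC, self.sigma2_E) < 0:
            raise ValueError("variance components must be >= 0")
        if self.condition_offsets is not None and len(self.condition_offsets) != self.n_conditions:
            raise ValueError("need one condition offset per condition")


def _accession_ids(n: int) -> list[str]:
    return [f"A{i + 1:03d}" for i in range(n)]


def _species_assignment(n: int) -> list[str]:
    """Assign species groups mirroring the panel composition; cycles if n != 180."""
    groups = [g for g, cnt in SPECIES_GROUPS.items() for _ in range(cnt)]
    return [groups[i % len(groups)] for i in range(n)]


def simulate_trait_table(
    params: SimulationParams,
    trait: str = "y",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one trait over the full balanced design, in long format.

    Returns columns ``accession, species_group, condition, replicate,
    trait, value`` with exactly n_accessions * n_conditions * n_reps rows.
    """
    g, c, r = params.n_accessions, params.n_conditions, params.n_reps
    if rng is None:
        rng = np.random.default_rng(params.seed)

    G = rng.normal(0.0, np.sqrt(params.sigma2_G), size=g)
    if params.condition_offsets is not None:
        C = np.asarray(params.condition_offsets, dtype=float)
    else:
        C = rng.normal(0.0, np.sqrt(params.sigma2_C), size=c)
    GC = rng.normal(0.0, np.sqrt(params.sigma2_GC), size=(g, c))
    E = rng.normal(0.0, np.sqrt(params.sigma2_E), size=(g, c, r))

    y = params.grand_mean + G[:, None, None] + C[None, :, None] + GC[:, :, None] + E

    acc = _accession_ids(g)
    species = _species_assignment(g)
    conditions = list(CONDITIONS[:c]) if c <= 2 else [f"cond{j + 1}" for j in range(c)]
    idx = pd.MultiIndex.from_product(
        [acc, conditions, range(1, r + 1)], names=["accession", "condition", "replicate"]
    )
    df = pd.DataFrame({"value": y.ravel()}, index=idx).reset_index()
    df.insert(1, "species_group", df["accession"].map(dict(zip(acc, species))))
    df.insert(4, "trait", trait)
    return df[["accession", "species_group", "condition", "replicate", "trait", "value"]]


#: Per-trait generative settings for the full 19-trait study simulation.
#: Relative variance shares (of the squared trait scale) chosen so that the
#: genotype term dominates for architectural/index traits and the condition
#: contrast dominates for biomass traits, qualitatively matching a drought
#: phenotyping experiment. ``cv`` sets the within-cell spread.
_STUDY_CV = {"default": 0.18, "PhE": 0.03, "RWC": 0.07, "NDVI": 0.08, "GLI": 0.08}


def simulate_study(
    seed: int = 0,
    n_accessions: int = 180,
    n_reps: int = 3,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate the full study: all 19 traits over the balanced design.

    Condition means per trait follow the published control/drought means,
    so the simulated table reproduces the study's sensitivity indices in
    expectation; genotype, interaction and residual variances are scaled to
    each trait via a coefficient of variation.
    """
    ref = table1_means()
    traits = traits if traits is not None else TRAITS
    rng = np.random.default_rng(seed)
    frames = []
    for trait in traits:
        mc = float(ref.loc[trait, "control_mean"])
        md = float(ref.loc[trait, "drought_mean"])
        mu = 0.5 * (mc + md)
        cv = _STUDY_CV.get(trait, _STUDY_CV["default"])
        scale2 = (cv * abs(mu)) ** 2 if mu != 0 else 1.0
        params = SimulationParams(
            n_accessions=n_accessions,
            n_reps=n_reps,
            grand_mean=mu,
            sigma2_G=0.5 * scale2,
            sigma2_GC=0.2 * scale2,
            sigma2_E=0.3 * scale2,
            condition_offsets=(mc - mu, md - mu),
            seed=seed,
        )
        frames.append(simulate_trait_table(params, trait=trait, rng=rng))
    return pd.concat(frames, ignore_index=True)
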