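"""Synthetic landscapes and sowing experiments with known filtering structure.

Real inputs for this kind of analysis are (a) percent-cover quadrat surveys
along soil pH and pine basal-area gradients and (b) counts of seedlings
emerging from equal-density sowings under crossed light x parent-material
treatments. Neither dataset is publicly deposited, so this module generates
both from an explicit environmental-filtering mechanism, keeping the truth
around for parameter-recovery tests.

Mechanism
---------
Each species carries three traits (seed mass, specific root length,
flowering date). On a standardized trait scale z, local fitness follows a
Gaussian kernel around an environment-dependent optimum that moves linearly
with (pH, basal area):

    fitness_i(env) = prod_j exp( -(z_ij - z*_j(env))^2 / (2 sigma^2) )

Smaller ``filter_strength`` (sigma) means harder filtering. The same kernel
drives both stages: quadrat covers are Dirichlet draws around the
fitness-proportional expected relative abundances, and greenhouse emergence
is binomial per species with probability proportional to fitness at the
treatment's (pH, basal area). Competition and dispersal are deliberately
absent: emergence is independent across species, as in a sowing experiment
with near-total post-emergence survival.

The default optimum maps slope so that seed mass falls with pH and rises
with basal area, while SRL and flowering date rise with pH and fall with
basal area — the qualitative trait-environment structure of ponderosa-pine
understory vegetation. Five "focal" species (the first five labels) are
anchored at spread-out trait positions so the 2x2 experiment has distinct,
treatment-dependent dominants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityMatrix, EnvironmentTable, TraitTable
from .errors import SpeciesLookupError, ValidationError

TRAITS = ("seed_mass", "srl", "flowering_date")

# generation scale: log for the two heavy-tailed size traits, raw for phenology
_LOG_TRAIT = {"seed_mass": True, "srl": True, "flowering_date": False}

# default trait-distribution parameters on the generation scale
_TRAIT_LOC = {"seed_mass": np.log(0.5), "srl": np.log(100.0), "flowering_date": 190.0}
_TRAIT_SCALE = {"seed_mass": 0.8, "srl": 0.5, "flowering_date": 25.0}

# optimum-map slopes in z units per unit of scaled environment
_OPTIMUM_COEFS = {
    "seed_mass": (-0.8, 0.8),  # (pH slope, basal-area slope)
    "srl": (1.0, -1.0),
    "flowering_date": (0.8, -1.0),
}

# z-space anchors for the five focal species: a full-sun specialist, a
# shade specialist, and three intermediates
_FOCAL_Z = np.array(
    [
        [-1.0, 1.3, 1.2],
        [0.8, -1.2, -1.2],
        [0.0, 0.3, 0.3],
        [-0.3, -0.5, -0.2],
        [1.2, 0.8, -0.5],
    ]
)

DEFAULT_TREATMENTS = pd.DataFrame(
    {
        "light": ["sun", "sun", "shade", "shade"],
        "soil": ["limestone", "basalt", "limestone", "basalt"],
        "soil_ph": [6.8, 5.9, 6.8, 5.9],
        "pine_ba": [0.0, 0.0, 59.0, 59.0],
    },
    index=pd.Index(
        ["sun-limestone", "sun-basalt", "shade-limestone", "shade-basalt"],
        name="treatment",
    ),
)


@dataclass(frozen=True)
class FitnessKernel:
    """Gaussian trait-filtering kernel shared by landscape and experiment."""

    trait_loc: dict = field(default_factory=lambda: dict(_TRAIT_LOC))
    trait_scale: dict = field(default_factory=lambda: dict(_TRAIT_SCALE))
    optimum_coefs: dict = field(default_factory=lambda: dict(_OPTIMUM_COEFS))
    filter_strength: float = 0.8
    ph_range: tuple = (5.5, 7.5)
    ba_range: tuple = (0.0, 59.0)

    def __post_init__(self):
        if self.filter_strength <= 0:
            raise ValidationError("filter_strength must be > 0")

    def _scaled_env(self, ph, ba):
        ph_mid = 0.5 * (self.ph_range[0] + self.ph_range[1])
        ph_half = 0.5 * (self.ph_range[1] - self.ph_range[0])
        ba_mid = 0.5 * (self.ba_range[0] + self.ba_range[1])
        ba_half = 0.5 * (self.ba_range[1] - self.ba_range[0])
        return (np.asarray(ph) - ph_mid) / ph_half, (np.asarray(ba) - ba_mid) / ba_half

    def z_optimum(self, ph, ba) -> np.ndarray:
        """Optimal z per trait at (ph, ba); shape (..., n_traits)."""
        u_ph, u_ba = self._scaled_env(ph, ba)
        return np.stack(
            [
                self.optimum_coefs[t][0] * u_ph + self.optimum_coefs[t][1] * u_ba
                for t in TRAITS
            ],
            axis=-1,
        )

    def z_scores(self, traits: TraitTable) -> np.ndarray:
        """Map natural-unit traits to the kernel's z scale (S x J)."""
        cols = []
        for t in TRAITS:
            v = traits.data[t].to_numpy(dtype=float)
            g = np.log(v) if _LOG_TRAIT[t] else v
            cols.append((g - self.trait_loc[t]) / self.trait_scale[t])
        return np.column_stack(cols)

    def fitness(self, traits: TraitTable, ph, ba) -> np.ndarray:
        """Relative fitness of each species at each environment (Q x S)."""
        z = self.z_scores(traits)  # S x J
        zopt = np.atleast_2d(self.z_optimum(ph, ba))  # Q x J
        d2 = ((z[None, :, :] - zopt[:, None, :]) ** 2).sum(axis=-1)
        return np.exp(-d2 / (2.0 * self.filter_strength**2))

    def traits_from_z(self, z: np.ndarray) -> dict:
        out = {}
        for j, t in enumerate(TRAITS):
            g = self.trait_loc[t] + z[:, j] * self.trait_scale[t]
            out[t] = np.exp(g) if _LOG_TRAIT[t] else g
        return out


@dataclass(frozen=True)
class LandscapeConfig:
    """Study conditions for the synthetic quadrat landscape."""

    n_species: int = 79
    n_quadrats: int = 96
    kernel: FitnessKernel = field(default_factory=FitnessKernel)
    noise_overdispersion: float = 1.0  # 1 = baseline Dirichlet noise; larger = noisier
    opening_fraction: float = 0.0  # share of quadrats in grass openings (pine BA exactly 0)
    total_cover_range: tuple = (40.0, 95.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 5:
            raise ValidationError("n_species must be >= 5 (five focal species)")
        if self.n_quadrats < 1:
            raise ValidationError("n_quadrats must be >= 1")
        if self.noise_overdispersion <= 0:
            raise ValidationError("noise_overdispersion must be > 0")


@dataclass(frozen=True)
class LandscapeTruth:
    kernel: FitnessKernel
    expected_relative: pd.DataFrame  # quadrat x species expected rel abundance
    species_z: pd.DataFrame  # species x trait z scores
    config: LandscapeConfig


@dataclass(frozen=True)
class LandscapeData:
    traits: TraitTable
    cover: CommunityMatrix
    env: EnvironmentTable
    truth: LandscapeTruth

    @property
    def too_small_for_fitting(self) -> bool:
        return self.truth.config.n_quadrats < 20


def generate_landscape(cfg: LandscapeConfig) -> LandscapeData:
    """Draw a trait-filtered quadrat landscape.

    Species traits are drawn once (the five focal species at fixed spread
    anchors plus jitter, the rest standard normal on the z scale); quadrat
    environments are uniform over the pH and basal-area ranges; expected
    relative abundance is fitness-proportional; realized cover is a
    Dirichlet draw around the expectation scaled to a random total percent
    cover. Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.kernel
    n_s, n_q = cfg.n_species, cfg.n_quadrats

    z = rng.standard_normal((n_s, len(TRAITS)))
    z[:5] = _FOCAL_Z + 0.05 * rng.standard_normal((5, len(TRAITS)))
    species = [f"sp{i + 1:03d}" for i in range(n_s)]
    traits = TraitTable(pd.DataFrame(k.traits_from_z(z), index=pd.Index(species, name="species_id")))

    ph = rng.uniform(*k.ph_range, n_q)
    ba = rng.uniform(*k.ba_range, n_q)
    # pine stands are interspersed with grass-dominated openings where
    # basal area is exactly zero; without them the BA gradient's low edge
    # would never be observed
    ba[rng.random(n_q) < cfg.opening_fraction] = k.ba_range[0]
    quadrats = [f"q{i + 1:03d}" for i in range(n_q)]
    env = EnvironmentTable(
        pd.DataFrame({"soil_ph": ph, "pine_ba": ba}, index=pd.Index(quadrats, name="sample_id"))
    )

    fit = k.fitness(traits, ph, ba)  # Q x S
    expected = fit / fit.sum(axis=1, keepdims=True)

    concentration = 200.0 / cfg.noise_overdispersion
    realized = np.vstack(
        [rng.dirichlet(np.maximum(expected[q] * concentration, 1e-6)) for q in range(n_q)]
    )
    totals = rng.uniform(*cfg.total_cover_range, n_q)
    cover = CommunityMatrix(
        pd.DataFrame(realized * totals[:, None], index=quadrats, columns=species),
        "cover",
    )

    truth = LandscapeTruth(
        kernel=k,
        expected_relative=pd.DataFrame(expected, index=quadrats, columns=species),
        species_z=pd.DataFrame(z, index=species, columns=list(TRAITS)),
        config=cfg,
    )
    return LandscapeData(traits=traits, cover=cover, env=env, truth=truth)


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for the 2x2 light x parent-material sowing experiment."""

    species_subset: tuple = ("sp001", "sp002", "sp003", "sp004", "sp005")
    treatments: pd.DataFrame = field(default_factory=lambda: DEFAULT_TREATMENTS.copy())
    pots_per_cell: tuple = (17, 16, 17, 16)  # aligned with treatments rows
    seeds_per_species: int = 12
    max_emergence: float = 0.7  # emergence probability of a perfectly matched species
    kernel: FitnessKernel = field(default_factory=FitnessKernel)
    seed: int = 0

    def __post_init__(self):
        if len(self.species_subset) < 2:
            raise ValidationError("need at least 2 species")
        if len(self.pots_per_cell) != len(self.treatments):
            raise ValidationError("pots_per_cell must align with treatments")
        if any(p < 1 for p in self.pots_per_cell):
            raise ValidationError("pots_per_cell must be >= 1")
        if self.seeds_per_species < 1:
            raise ValidationError("seeds_per_species must be >= 1")
        if not 0 < self.max_emergence <= 1:
            raise ValidationError("max_emergence must be in (0, 1]")


@dataclass(frozen=True)
class ExperimentTruth:
    emergence_prob: pd.DataFrame  # treatment x species
    expected_relative: pd.DataFrame  # treatment x species, fitness-normalized


@dataclass(frozen=True)
class ExperimentData:
    counts: CommunityMatrix  # pot x species seedling counts
    design: pd.DataFrame  # pot -> treatment, light, soil, soil_ph, pine_ba
    truth: ExperimentTruth

    @property
    def treatments(self) -> pd.Series:
        return self.design["treatment"]


def generate_experiment(traits: TraitTable, cfg: ExperimentConfig) -> ExperimentData:
    """Sow the focal species into replicated pots and draw emergence counts.

    Per pot, each species' seedling count is Binomial(seeds_per_species,
    max_emergence * fitness at the treatment's (pH, basal area)) —
    independent across species. Pots where nothing emerges are retained
    (flagged via ``counts.zero_rows``) so the downstream exclusion rule
    stays explicit.
    """
    sub = traits.subset(cfg.species_subset)
    missing = [s for s in cfg.species_subset if s not in traits.data.index]
    if missing:
        raise SpeciesLookupError(missing)
    rng = np.random.default_rng(cfg.seed)
    k = cfg.kernel

    fit = k.fitness(sub, cfg.treatments["soil_ph"].to_numpy(), cfg.treatments["pine_ba"].to_numpy())
    prob = cfg.max_emergence * fit  # treatment x species
    totals = fit.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        # NaN where no species has measurable fitness (nothing can emerge)
        expected_rel = np.where(totals > 0, fit / np.where(totals > 0, totals, 1.0), np.nan)

    rows, meta = [], []
    for t_idx, (label, trow) in enumerate(cfg.treatments.iterrows()):
        for pot in range(cfg.pots_per_cell[t_idx]):
            counts = rng.binomial(cfg.seeds_per_species, prob[t_idx])
            pot_id = f"{label}-pot{pot + 1:02d}"
            rows.append(pd.Series(counts, index=list(cfg.species_subset), name=pot_id))
            meta.append(
                {
                    "sample_id": pot_id,
                    "treatment": label,
                    "light": trow["light"],
                    "soil": trow["soil"],
                    "soil_ph": trow["soil_ph"],
                    "pine_ba": trow["pine_ba"],
                }
            )
    counts = CommunityMatrix(pd.DataFrame(rows), "count")
    design = pd.DataFrame(meta).set_index("sample_id")
    truth = ExperimentTruth(
        emergence_prob=pd.DataFrame(
            prob, index=cfg.treatments.index, columns=list(cfg.species_subset)
        ),
        expected_relative=pd.DataFrame(
            expected_rel, index=cfg.treatments.index, columns=list(cfg.species_subset)
        ),
    )
    return ExperimentData(counts=counts, design=design, truth=truth)
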