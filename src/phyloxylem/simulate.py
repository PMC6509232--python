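"""Synthetic phylogeny / climate / trait generator with known parameters.

Every pipeline stage is testable without external data: a Yule tree
rescaled to a fixed age stands in for the time-calibrated phylogeny,
climate indices are linear in a species' midpoint latitude plus correlated
Gaussian noise (thermal indices decline with latitude, moisture indices
co-vary with them), and tissue fractions follow the generative mirror of
the regression model analysed downstream —

    sqrt(CF_percent) = intercept + X_climate beta + eps,
    eps ~ MVN(0, sigma^2 * C(lambda)) via Cholesky of the
    lambda-transformed phylogenetic covariance

— then squared back to percent.  Total parenchyma is derived as
RAF = RF + AF, as in real tables.  Vessel area A and density N are
generated on the log10 scale with opposing latitude trends so that the
composition metrics F = A N and S = A / N show the expected opposite
latitudinal slopes.  All randomness flows from a single integer seed and
the full ground truth is recorded with each dataset.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Phylogeny, lambda_transform
from .traits import CLIMATE_INDICES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClimateIndexModel:
    """Linear latitude response of one climate index."""

    intercept: float
    lat_slope: float
    noise_sd: float


@dataclass(frozen=True)
class TraitModel:
    """Generative model of one tissue fraction on the sqrt-percent scale."""

    intercept: float
    betas: dict[str, float] = field(default_factory=dict)
    lam: float = 1.0
    sigma2: float = 0.01  # Brownian rate, (sqrt-percent)^2 per My


# latitude responses chosen to emulate an eastern-monsoonal gradient from
# tropical (~18 deg N) to cold-temperate (~54 deg N) conditions
DEFAULT_CLIMATE_MODELS: dict[str, ClimateIndexModel] = {
    "MAT": ClimateIndexModel(34.0, -0.67, 1.2),
    "ABT": ClimateIndexModel(30.0, -0.50, 1.0),
    "PET": ClimateIndexModel(1650.0, -19.4, 50.0),
    "WI": ClimateIndexModel(307.0, -4.86, 12.0),
    "CI": ClimateIndexModel(35.0, -1.94, 6.0),
    "MTWM": ClimateIndexModel(31.0, -0.17, 1.2),
    "MTCM": ClimateIndexModel(34.5, -1.08, 1.8),
    "MAP": ClimateIndexModel(2448.0, -36.0, 150.0),
    "PWQ": ClimateIndexModel(1050.0, -13.9, 80.0),
    "PCQ": ClimateIndexModel(440.0, -7.8, 40.0),
    "AET": ClimateIndexModel(1424.0, -18.0, 60.0),
    "Im": ClimateIndexModel(30.0, -0.55, 4.0),
    "NPP": ClimateIndexModel(2050.0, -30.6, 120.0),
}

# tissue-fraction models: lambdas and magnitudes in the range reported for
# real wood-anatomical data; vessels gain and fibers lose area toward
# colder (high-latitude, low-MAT) conditions, axial parenchyma carries no
# climate effect
DEFAULT_TRAIT_MODELS: dict[str, TraitModel] = {
    "VF": TraitModel(6.1, {"MAT": -0.06}, lam=0.85, sigma2=0.008),
    "FF": TraitModel(8.3, {"MAT": 0.05}, lam=0.73, sigma2=0.006),
    "RF": TraitModel(6.1, {"MTCM": 0.02}, lam=0.67, sigma2=0.006),
    "AF": TraitModel(2.8, {}, lam=0.90, sigma2=0.010),
}

# residual (evolutionary) correlations among the sqrt-scale trait noises;
# the VF/FF entry mirrors the vessel-fiber space trade-off
DEFAULT_TRAIT_CORR = pd.DataFrame(
    [
        [1.00, -0.70, -0.05, 0.00],
        [-0.70, 1.00, -0.40, -0.20],
        [-0.05, -0.40, 1.00, -0.10],
        [0.00, -0.20, -0.10, 1.00],
    ],
    index=["VF", "FF", "RF", "AF"],
    columns=["VF", "FF", "RF", "AF"],
)

# log10 vessel area (mm^2) and density (mm^-2): smaller, denser vessels
# toward high latitude
DEFAULT_VESSEL_MODELS = {
    "logA": ClimateIndexModel(-2.0, -0.012, 0.15),
    "logN": ClimateIndexModel(1.2, 0.016, 0.15),
}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_tips: int = 300
    tree_depth: float = 100.0
    birth_rate: float = 1.0
    seed: int = 0
    lat_range: tuple[float, float] = (18.0, 54.0)
    lon_range: tuple[float, float] = (98.0, 122.0)
    climate_models: dict[str, ClimateIndexModel] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_MODELS)
    )
    climate_noise_corr: float = 0.5
    trait_models: dict[str, TraitModel] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MODELS)
    )
    trait_corr: pd.DataFrame | None = None  # None -> DEFAULT_TRAIT_CORR subset
    vessel_models: dict[str, ClimateIndexModel] = field(
        default_factory=lambda: dict(DEFAULT_VESSEL_MODELS)
    )

    def __post_init__(self):
        if self.n_tips < 10:
            raise ValueError("n_tips must be >= 10")
        for name, tm in self.trait_models.items():
            if not 0.0 <= tm.lam <= 1.0:
                raise ValueError(f"lambda of {name} outside [0, 1]")
            if tm.sigma2 <= 0:
                raise ValueError(f"sigma2 of {name} must be positive")
        for name, cm in self.climate_models.items():
            if cm.noise_sd <= 0:
                raise ValueError(f"noise sd of {name} must be positive")

    def ground_truth(self) -> dict:
        gt = dataclasses.asdict(self)
        gt["trait_corr"] = (
            self.trait_corr if self.trait_corr is not None else DEFAULT_TRAIT_CORR
        ).to_dict()
        gt["derived"] = {"RAF": "RF + AF (percent scale)"}
        return _jsonable(gt)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass(frozen=True)
class SyntheticDataset:
    tree: Phylogeny
    table: pd.DataFrame
    ground_truth: dict


# -- tree ------------------------------------------------------------------


def simulate_tree(cfg: SimConfig) -> Phylogeny:
    """Yule (pure-birth) tree with ``cfg.n_tips`` extant tips, rescaled so
    every root-to-tip path equals ``cfg.tree_depth`` My.

    Simulated forward in time: starting from two lineages, exponential
    waiting times (rate k * birth_rate for k active lineages) separate
    successive random splits; after the n-th lineage appears one further
    exponential waiting time (rate n * birth_rate) runs to the present, so
    pendant edges are strictly positive and the covariance matrix is
    nonsingular.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tips
    b = cfg.birth_rate
    # node = [birth_time, children or None]
    root_children = [[0.0, None], [0.0, None]]
    active = list(root_children)
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * b))
        idx = rng.integers(k)
        node = active.pop(idx)
        kids = [[t, None], [t, None]]
        node[1] = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / (n * b))
    scale = cfg.tree_depth / t_end

    counter = [0]

    def newick(node):
        # a node is the lineage segment from its birth to its split (or to
        # the present); the newick edge above a clade is that segment
        birth, kids = node
        if kids is None:
            counter[0] += 1
            return f"sp{counter[0]:04d}:{(t_end - birth) * scale!r}"
        inner = ",".join(newick(k) for k in kids)
        return f"({inner}):{(kids[0][0] - birth) * scale!r}"

    parts = ",".join(newick(c) for c in root_children)
    return Phylogeny.from_string(f"({parts});")


# -- climate ---------------------------------------------------------------


def simulate_climate(tips: list[str], cfg: SimConfig) -> pd.DataFrame:
    """Latitude/longitude midpoints plus climate indices linear in latitude
    with equicorrelated Gaussian noise across indices."""
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(tips)
    lat = rng.uniform(*cfg.lat_range, size=n)
    lon = rng.uniform(*cfg.lon_range, size=n)
    names = [c for c in CLIMATE_INDICES if c in cfg.climate_models]
    names += [c for c in cfg.climate_models if c not in names]
    k = len(names)
    rho = cfg.climate_noise_corr
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        Lc = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"climate noise correlation {rho} is not PSD") from exc
    z = rng.standard_normal((n, k)) @ Lc.T
    data = {"lat_mid": lat, "lon_mid": lon}
    for j, name in enumerate(names):
        m = cfg.climate_models[name]
        data[name] = m.intercept + m.lat_slope * lat + m.noise_sd * z[:, j]
    return pd.DataFrame(data, index=pd.Index(tips, name="species"))


# -- traits ----------------------------------------------------------------


def simulate_traits(
    tree: Phylogeny, climate: pd.DataFrame, cfg: SimConfig
) -> pd.DataFrame:
    """Tissue fractions (percent), vessel area A (mm^2) and density N
    (mm^-2) for the tips of ``tree`` given simulated climate.

    Noise construction: i.i.d. standard normal tip draws are first mixed
    across traits by the Cholesky factor of the trait correlation matrix,
    then each trait's column is structured along the tree by the Cholesky
    factor of its own lambda-transformed covariance.  When two traits share
    the same lambda their contrast-level correlation equals the requested
    one exactly; otherwise approximately.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    tips = tree.tip_labels
    climate = climate.loc[tips]
    n = len(tips)
    C = tree.vcv().subset(tips).matrix

    trait_names = list(cfg.trait_models)
    corr = cfg.trait_corr
    if corr is None:
        corr = DEFAULT_TRAIT_CORR
    corr = corr.loc[trait_names, trait_names].to_numpy()
    Lt = np.linalg.cholesky(corr)
    Z = rng.standard_normal((n, len(trait_names))) @ Lt.T

    sqrt_traits = {}
    clipped = 0
    for j, name in enumerate(trait_names):
        tm = cfg.trait_models[name]
        V = lambda_transform(C, tm.lam)
        Lv = np.linalg.cholesky(V + 1e-10 * np.eye(n))
        eps = np.sqrt(tm.sigma2) * (Lv @ Z[:, j])
        mean = np.full(n, tm.intercept)
        for var, beta in tm.betas.items():
            mean = mean + beta * climate[var].to_numpy()
        s = mean + eps
        lo = (s < 0).sum()
        hi = (s > 10).sum()
        clipped += lo + hi
        sqrt_traits[name] = np.clip(s, 0.0, 10.0)
    total = n * len(trait_names)
    if clipped:
        logger.warning("clipped %d/%d sqrt-scale trait values", clipped, total)
        if clipped > 0.05 * total:
            logger.warning("more than 5%% of values clipped; parameters unrealistic")

    table = pd.DataFrame(
        {name: sqrt_traits[name] ** 2 for name in trait_names},
        index=pd.Index(tips, name="species"),
    )
    if {"RF", "AF"} <= set(table.columns):
        table["RAF"] = table["RF"] + table["AF"]

    lat = climate["lat_mid"].to_numpy()
    am = cfg.vessel_models["logA"]
    nm = cfg.vessel_models["logN"]
    logA = am.intercept + am.lat_slope * lat + am.noise_sd * rng.standard_normal(n)
    logN = nm.intercept + nm.lat_slope * lat + nm.noise_sd * rng.standard_normal(n)
    table["A"] = 10.0**logA
    table["N"] = 10.0**logN
    table.attrs["n_clipped"] = int(clipped)
    return table


def simulate_dataset(cfg: SimConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate a complete tree + trait/climate table with ground truth.

    Keyword overrides are applied to a fresh :class:`SimConfig`.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    tree = simulate_tree(cfg)
    climate = simulate_climate(tree.tip_labels, cfg)
    traits = simulate_traits(tree, climate, cfg)
    table = pd.concat([traits, climate], axis=1)
    return SyntheticDataset(tree=tree, table=table, ground_truth=cfg.ground_truth())
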