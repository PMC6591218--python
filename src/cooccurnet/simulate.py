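"""Synthetic size-fractionated marine OTU tables with planted structure.

The generator emulates the sampling design of a coastal time series:
a factorial grid of months × stations × depth layers, each water sample
split into three plankton size fractions (FL, NP, MP).  Community structure
is planted through a latent-factor model: each module *m* has a per-site
factor

    f_m(site) = alpha_m * depth_code + beta * z(env driver) + gamma_m(month) + eta,

with ``depth_code`` = 0 / 0.5 / 1 for surface / middle / bottom,
``eta ~ N(0, 1)`` idiosyncratic site noise, and module-specific month
effects ``gamma_m(month) ~ N(0, month_sd)``.  OTU *i* of module *m* has
log-abundance ``base_i + loading_i * f_m + eps_i`` with
``eps ~ N(0, noise_sd)``.  The factor is standardized per module so the
loadings alone set the planted correlation strengths.  The planted hub is
the max-loading member: its loading is raised by ``hub_boost`` and its
idiosyncratic noise shrunk by ``hub_noise_scale``, so the hub tracks the
module factor much more faithfully than ordinary members.  At the default
rho >= 0.7 edge threshold this makes modules star-like around their hub
(hub-member correlations pass, most member-member correlations do not),
and hubs are recoverable from within-module degree.  Background OTUs are
independent log-normals.
Counts are drawn multinomially per sample with a fixed library size, so
the table is compositional: every column sums to ``reads_per_sample``
exactly.

Reproducibility: each operation owns one RNG stream, created as
``numpy.random.default_rng([OP_CODE, seed])`` with OP_CODE 0 for the
environment, 1 for counts and 2 for taxonomy.  Environment and counts are
therefore independently reproducible from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import DEPTHS, FRACTIONS, MONTHS, OtuTable, RANKS

_OP_ENV = 0
_OP_COUNTS = 1
_OP_TAXONOMY = 2

#: depth-layer encodings used by module depth preferences
DEPTH_CODE = {"surface": 0.0, "middle": 0.5, "bottom": 1.0}

#: per-depth (mean, sd, clip_lo, clip_hi) for each environmental variable
ENV_PROFILES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "temperature": {
        "surface": (21.8, 4.5, 14.1, 29.7),
        "middle": (20.0, 3.9, 14.1, 29.7),
        "bottom": (18.2, 3.4, 14.1, 29.7),
    },
    "salinity": {
        "surface": (32.1, 1.4, 29.0, 34.4),
        "middle": (32.75, 1.2, 29.0, 34.4),
        "bottom": (33.4, 1.0, 29.0, 34.4),
    },
    "NOx": {
        "surface": (2.0, 1.6, 0.02, 6.77),
        "middle": (3.2, 2.2, 0.10, 9.00),
        "bottom": (4.5, 2.8, 0.17, 12.04),
    },
    "phosphate": {
        "surface": (0.25, 0.15, 0.01, 2.5),
        "middle": (0.40, 0.20, 0.01, 2.5),
        "bottom": (0.60, 0.25, 0.01, 2.5),
    },
    "silicate": {
        "surface": (5.0, 3.0, 0.1, 30.0),
        "middle": (9.0, 4.0, 0.1, 30.0),
        "bottom": (13.0, 5.0, 0.1, 30.0),
    },
    "DO": {
        "surface": (8.5, 0.9, 3.0, 12.0),
        "middle": (7.5, 0.9, 3.0, 12.0),
        "bottom": (6.5, 0.9, 3.0, 12.0),
    },
    "pH": {
        "surface": (8.15, 0.08, 7.6, 8.4),
        "middle": (8.05, 0.08, 7.6, 8.4),
        "bottom": (7.95, 0.08, 7.6, 8.4),
    },
    "Chl_a": {
        "surface": (2.0, 1.2, 0.05, 8.0),
        "middle": (1.5, 1.0, 0.05, 8.0),
        "bottom": (0.8, 0.6, 0.05, 8.0),
    },
}

#: module depth preferences cycle through these labels
_DEPTH_PREFS = ("S", "MB", "W")
#: environmental drivers assigned to modules, in cycling order (None = no driver)
_ENV_DRIVERS = ("temperature", "NOx", "phosphate", "silicate", "salinity", None)

_PHYLA = (
    "Proteobacteria", "Bacteroidetes", "Actinobacteria",
    "Planctomycetes", "Cyanobacteria", "Marinimicrobia",
)
_FAMILIES = {
    "Proteobacteria": ("Rhodobacteraceae", "Halomonadaceae"),
    "Bacteroidetes": ("Flavobacteriaceae", "Cryomorphaceae"),
    "Actinobacteria": ("Microbacteriaceae", "Acidimicrobiaceae"),
    "Planctomycetes": ("Planctomycetaceae", "Phycisphaeraceae"),
    "Cyanobacteria": ("Cyanobiaceae", "Nostocaceae"),
    "Marinimicrobia": ("SAR406-cladeFam", "MarinimicrobiaFam"),
}


@dataclass
class SimConfig:
    """Configuration of the synthetic community generator.

    Defaults reproduce the study design: 5 months × 6 stations × 3 depth
    layers × 3 size fractions (270 samples), six planted modules of ten
    OTUs each plus independent background OTUs.
    """

    n_months: int = 5
    n_stations: int = 6
    n_depths: int = 3
    fractions: tuple[str, ...] = FRACTIONS
    n_modules: int = 6
    otus_per_module: int = 10
    n_background_otus: int = 40
    loading_mean: float = 0.35
    noise_sd: float = 0.25
    reads_per_sample: int = 100_000
    env_link_strength: float = 0.5
    seed: int = 0
    # factor-model weights (see module docstring)
    hub_boost: float = 1.2
    hub_noise_scale: float = 0.0
    loading_spread: float = 0.05
    depth_effect: float = 0.5
    month_sd: float = 0.3
    env_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_months", "n_stations", "n_depths", "n_modules",
                     "otus_per_module"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_otus < 0:
            raise ValueError("n_background_otus must be >= 0")
        if self.otus_per_module < 2:
            raise ValueError("need at least 2 OTUs per module")
        if self.noise_sd < 0 or self.env_sd_scale < 0:
            raise ValueError("noise scales must be >= 0")
        if self.reads_per_sample < 100:
            raise ValueError("reads_per_sample must be >= 100")
        if self.n_months > len(MONTHS):
            raise ValueError(f"at most {len(MONTHS)} months supported")
        if self.n_depths > len(DEPTHS):
            raise ValueError(f"at most {len(DEPTHS)} depth layers supported")
        self.fractions = tuple(self.fractions)

    @property
    def months(self) -> tuple[str, ...]:
        return MONTHS[: self.n_months]

    @property
    def depths(self) -> tuple[str, ...]:
        return DEPTHS[: self.n_depths]

    @property
    def stations(self) -> tuple[str, ...]:
        return tuple(f"ST{i + 1}" for i in range(self.n_stations))

    @property
    def n_samples(self) -> int:
        return (self.n_months * self.n_stations * self.n_depths
                * len(self.fractions))

    @classmethod
    def strong_signal(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Single-fraction strong-signal design: 6 modules × 10 OTUs over a
        90-sample grid (5 months × 6 stations × 3 depths, FL only)."""
        kw = dict(fractions=("FL",), seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        kw = {k: v for k, v in mapping.items() if k in known}
        if "fractions" in kw and isinstance(kw["fractions"], str):
            kw["fractions"] = (kw["fractions"],)
        return cls(**kw)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic OTU table."""

    module_of_otu: dict[str, int]
    hub_flags: set[str]
    depth_preference_of_module: dict[int, str]
    env_driver_of_module: dict[int, str | None]

    @property
    def modules(self) -> list[int]:
        return sorted(self.depth_preference_of_module)

    def members(self, module: int) -> list[str]:
        return [o for o, m in self.module_of_otu.items() if m == module]

    def planted_pairs(self) -> list[tuple[str, str]]:
        """All within-module OTU pairs."""
        pairs = []
        for m in self.modules:
            mem = self.members(m)
            pairs.extend(
                (a, b) for i, a in enumerate(mem) for b in mem[i + 1:]
            )
        return pairs

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for otu in sorted(self.module_of_otu):
            rows.append((otu, "module", str(self.module_of_otu[otu])))
        for otu in sorted(self.hub_flags):
            rows.append((otu, "hub", "1"))
        for mod in self.modules:
            rows.append((f"module_{mod}", "depth_preference",
                         self.depth_preference_of_module[mod]))
            drv = self.env_driver_of_module.get(mod)
            rows.append((f"module_{mod}", "env_driver",
                         "" if drv is None else drv))
        pd.DataFrame(rows, columns=["entity", "key", "value"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        module_of_otu, hubs, prefs, drivers = {}, set(), {}, {}
        for _, (entity, key, value) in df.iterrows():
            if key == "module":
                module_of_otu[entity] = int(value)
            elif key == "hub":
                hubs.add(entity)
            elif key == "depth_preference":
                prefs[int(entity.split("_")[1])] = value
            elif key == "env_driver":
                drivers[int(entity.split("_")[1])] = value or None
        return cls(module_of_otu, hubs, prefs, drivers)


# ---------------------------------------------------------------------------
# sampling grid & environment
# ---------------------------------------------------------------------------

def _rng(seed: int, op_code: int) -> np.random.Generator:
    return np.random.default_rng([op_code, int(seed)])


def sample_grid(config: SimConfig) -> pd.DataFrame:
    """Per-sample metadata for the full factorial design (fixed order:
    month, station, depth, fraction)."""
    rows = []
    for month in config.months:
        for station in config.stations:
            for depth in config.depths:
                for frac in config.fractions:
                    sid = f"{month}-{station}-{depth}-{frac}"
                    rows.append((sid, month, station, depth, frac))
    df = pd.DataFrame(rows, columns=["sample_id", "month", "station",
                                     "depth", "fraction"])
    return df.set_index("sample_id")


def generate_env(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw per-sample environmental parameters from depth-dependent
    distributions (clipped normals; one water mass per month × station ×
    depth shared by its size fractions)."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _OP_ENV)
    meta = sample_grid(config)
    sites = meta[["month", "station", "depth"]].drop_duplicates()
    values = {}
    for var, profiles in ENV_PROFILES.items():
        col = np.empty(len(sites))
        for i, depth in enumerate(sites["depth"]):
            mean, sd, lo, hi = profiles[depth]
            col[i] = np.clip(rng.normal(mean, sd * config.env_sd_scale), lo, hi)
        values[var] = col
    site_env = pd.DataFrame(values, index=pd.MultiIndex.from_frame(sites))
    keys = pd.MultiIndex.from_frame(meta[["month", "station", "depth"]])
    env = site_env.loc[keys]
    env.index = meta.index
    return env


# ---------------------------------------------------------------------------
# planted-community counts
# ---------------------------------------------------------------------------

def _module_layout(config: SimConfig) -> GroundTruth:
    module_of_otu: dict[str, int] = {}
    prefs: dict[int, str] = {}
    drivers: dict[int, str | None] = {}
    for m in range(1, config.n_modules + 1):
        prefs[m] = _DEPTH_PREFS[(m - 1) % len(_DEPTH_PREFS)]
        drivers[m] = _ENV_DRIVERS[(m - 1) % len(_ENV_DRIVERS)]
        for k in range(config.otus_per_module):
            otu = f"OTU_{(m - 1) * config.otus_per_module + k + 1:04d}"
            module_of_otu[otu] = m
    return GroundTruth(module_of_otu, set(), prefs, drivers)


def _latent(config: SimConfig, env: pd.DataFrame, meta: pd.DataFrame,
            rng: np.random.Generator) -> tuple[pd.DataFrame, GroundTruth]:
    gt = _module_layout(config)
    site_key = meta[["month", "station", "depth"]]
    sites = site_key.drop_duplicates()
    n_sites = len(sites)
    site_index = pd.MultiIndex.from_frame(sites)
    sample_to_site = pd.MultiIndex.from_frame(site_key)
    site_pos = pd.Series(np.arange(n_sites), index=site_index)
    pos = site_pos.loc[sample_to_site].to_numpy()

    depth_code = sites["depth"].map(DEPTH_CODE).to_numpy()
    first_sample = (pd.Series(meta.index, index=sample_to_site)
                    .groupby(level=[0, 1, 2], sort=False).first())
    env_sites = env.loc[first_sample.loc[site_index]]

    alpha_of_pref = {"S": -config.depth_effect, "MB": config.depth_effect,
                     "W": 0.0}
    n_mod_otus = config.n_modules * config.otus_per_module
    otu_ids = [f"OTU_{i + 1:04d}"
               for i in range(n_mod_otus + config.n_background_otus)]

    x = np.empty((len(otu_ids), len(meta)))
    row = 0
    for m in range(1, config.n_modules + 1):
        alpha = alpha_of_pref[gt.depth_preference_of_module[m]]
        driver = gt.env_driver_of_module[m]
        f = alpha * depth_code
        if driver is not None and config.env_link_strength != 0:
            v = env_sites[driver].to_numpy(dtype=float)
            spread = v.std()
            z = (v - v.mean()) / spread if spread > 0 else np.zeros(n_sites)
            f = f + config.env_link_strength * z
        month_eff = rng.normal(0.0, config.month_sd, size=config.n_months)
        month_pos = {mo: i for i, mo in enumerate(config.months)}
        f = f + month_eff[[month_pos[mo] for mo in sites["month"]]]
        f = f + rng.normal(0.0, 1.0, size=n_sites)
        # standardize so every module has the same signal scale and the
        # loadings alone set the planted correlation strengths
        if f.std() > 0:
            f = (f - f.mean()) / f.std()

        loadings = config.loading_mean * rng.uniform(
            1 - config.loading_spread, 1 + config.loading_spread,
            size=config.otus_per_module)
        hub_local = int(np.argmax(loadings))
        loadings[hub_local] *= config.hub_boost
        bases = rng.normal(0.0, 0.5, size=config.otus_per_module)
        eps = rng.normal(0.0, config.noise_sd,
                         size=(config.otus_per_module, len(meta)))
        # the hub tracks its module factor with less idiosyncratic noise
        eps[hub_local] *= config.hub_noise_scale
        x[row:row + config.otus_per_module] = (
            bases[:, None] + loadings[:, None] * f[pos][None, :] + eps
        )
        gt.hub_flags.add(otu_ids[row + hub_local])
        row += config.otus_per_module

    if config.n_background_otus:
        bases = rng.normal(0.0, 0.5, size=config.n_background_otus)
        x[row:] = bases[:, None] + rng.normal(
            0.0, 0.8, size=(config.n_background_otus, len(meta)))

    latent = pd.DataFrame(x, index=otu_ids, columns=meta.index)
    return latent, gt


def latent_log_abundance(
    config: SimConfig, env: pd.DataFrame, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Latent OTU × sample log-abundance matrix before multinomial
    resampling (useful for noise-free checks of the planted structure)."""
    seed = config.seed if seed is None else seed
    meta = sample_grid(config)
    return _latent(config, env, meta, _rng(seed, _OP_COUNTS))


def generate_counts(
    config: SimConfig, env: pd.DataFrame, seed: int | None = None
) -> tuple[OtuTable, GroundTruth]:
    """Draw the OTU count table: multinomial closure of the exponentiated
    latent abundances, one draw of ``reads_per_sample`` reads per sample."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _OP_COUNTS)
    meta = sample_grid(config)
    if list(env.index) != list(meta.index):
        raise ValueError("env table does not match the configured sample grid")
    latent, gt = _latent(config, env, meta, rng)
    x = latent.to_numpy()
    # per-sample softmax: compositional closure before sequencing
    x = x - x.max(axis=0, keepdims=True)
    p = np.exp(x)
    p /= p.sum(axis=0, keepdims=True)
    counts = np.empty(x.shape, dtype=np.int64)
    for j in range(x.shape[1]):
        counts[:, j] = rng.multinomial(config.reads_per_sample, p[:, j])
    table = OtuTable(pd.DataFrame(counts, index=latent.index,
                                  columns=latent.columns))
    return table, gt


def generate_taxonomy(
    config: SimConfig, ground_truth: GroundTruth, seed: int | None = None
) -> pd.DataFrame:
    """Assign a Silva-style lineage per OTU; module mates share a phylum
    with high probability so that same-phylum edges dominate, as observed
    in real co-occurrence networks."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _OP_TAXONOMY)
    module_phylum = {
        m: _PHYLA[(m - 1) % len(_PHYLA)] for m in ground_truth.modules
    }
    n_total = (config.n_modules * config.otus_per_module
               + config.n_background_otus)
    rows = []
    for i in range(n_total):
        otu = f"OTU_{i + 1:04d}"
        mod = ground_truth.module_of_otu.get(otu)
        if mod is not None and rng.uniform() < 0.7:
            phylum = module_phylum[mod]
        else:
            phylum = _PHYLA[rng.integers(len(_PHYLA))]
        family = _FAMILIES[phylum][int(rng.integers(2))]
        rows.append({
            "otu_id": otu,
            "domain": "Bacteria",
            "phylum": phylum,
            "class": f"{phylum}_cls",
            "order": f"{family[:-4]}ales",
            "family": family,
            "genus": "unclassified",
        })
    return pd.DataFrame(rows).set_index("otu_id")[list(RANKS)]


def simulate_bundle(config: SimConfig, seed: int | None = None):
    """Convenience: environment + counts + taxonomy + metadata in one call.

    Returns ``(AnalysisBundle, GroundTruth)``.
    """
    from .tables import AnalysisBundle

    seed = config.seed if seed is None else seed
    env = generate_env(config, seed)
    table, gt = generate_counts(config, env, seed)
    taxonomy = generate_taxonomy(config, gt, seed)
    meta = sample_grid(config)
    return AnalysisBundle(otu=table, meta=meta, env=env,
                          taxonomy=taxonomy), gt
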