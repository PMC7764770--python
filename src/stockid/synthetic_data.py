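"""Synthetic genotype and contaminant datasets with the statistical
structure the downstream analyses assume.

Genotypes follow the Balding–Nichols model: each locus draws an ancestral
alt-allele frequency p, each cluster then draws its own frequency from a
Beta distribution with mean p and variance p(1-p)F, so the divergence
parameter F is (in expectation) the F_ST the pipeline later estimates.
Site-level structure, when requested, is nested: site frequencies are drawn
around their cluster's frequency with a (typically much smaller) site-level
F, emulating strong cluster divergence with very weak differentiation
among fishing sites within a cluster. Loci are independent; there is no
linkage.

Contaminants are log-normal: log concentration = log baseline + log species
effect + log region effect + age * slope + Normal(0, sigma). Values below
the detection limit are recorded as non-detects with the limit retained,
mimicking left-censored laboratory reporting. Congener profiles spread a
fish's total PCB burden over a configurable congener set with extra weight
on a dominant subset (defaults: 110, 153, 118, 138, the peaks typical of
legacy Aroclor mixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable
from .contaminant_stats import ContaminantTable

__all__ = [
    "GenotypeSimConfig",
    "ContaminantSimConfig",
    "simulate_genotypes",
    "inject_missingness",
    "simulate_contaminants",
]

_CLUSTER_NAMES = ("Northern", "Southern")


@dataclass
class GenotypeSimConfig:
    """Parameters of the two-level Balding–Nichols genotype simulator.

    Defaults reproduce the reference dataset shape the assignment study
    assumes: two clusters of 174 samples at 3055 biallelic loci with
    low-to-moderate divergence and a few percent missing calls.
    """

    n_clusters: int = 2
    samples_per_cluster: int = 174
    n_loci: int = 3055
    fst: float = 0.10
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    sites_per_cluster: int | None = None
    site_fst: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if not (0.0 <= self.site_fst < 1.0):
            raise ValueError("site_fst must be in [0, 1)")
        if self.samples_per_cluster < 1 or self.n_loci < 1:
            raise ValueError("need >= 1 sample per cluster and >= 1 locus")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must sit inside (0, 1)")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     f: float) -> np.ndarray:
    """Draw descendant frequencies around p with E[var] = p(1-p)f."""
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    alpha, beta = p * scale, (1.0 - p) * scale
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("degenerate Beta parameters; check fst and freqs")
    return rng.beta(alpha, beta)


def simulate_genotypes(cfg: GenotypeSimConfig) -> tuple[GenotypeMatrix, SampleTable]:
    """Simulate genotypes and metadata under the nested Balding–Nichols model.

    Clusters are labelled "Northern", "Southern", then "C3"...; sites are
    "<cluster>_<k>". Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_loci)

    cluster_names = [
        _CLUSTER_NAMES[i] if i < len(_CLUSTER_NAMES) else f"C{i + 1}"
        for i in range(cfg.n_clusters)
    ]
    sample_ids: list[str] = []
    clusters: list[str] = []
    sites: list[str] = []
    blocks: list[np.ndarray] = []

    for ci, cname in enumerate(cluster_names):
        p_cluster = _balding_nichols(rng, p_anc, cfg.fst)
        n = cfg.samples_per_cluster
        if cfg.sites_per_cluster:
            k = cfg.sites_per_cluster
            # round-robin so every site gets >= floor(n/k) samples
            site_of = np.arange(n) % k
            p_sites = np.stack([
                _balding_nichols(rng, p_cluster, cfg.site_fst)
                for _ in range(k)
            ])
            freqs = p_sites[site_of]  # (n, n_loci)
            sample_sites = [f"{cname}_{s + 1}" for s in site_of]
        else:
            freqs = np.broadcast_to(p_cluster, (n, cfg.n_loci))
            sample_sites = [f"{cname}_1"] * n
        geno = rng.binomial(2, freqs).astype(np.int8)
        blocks.append(geno)
        sample_ids.extend(f"{cname[:1]}{ci + 1}_{i + 1:04d}" for i in range(n))
        clusters.extend([cname] * n)
        sites.extend(sample_sites)

    calls = np.vstack(blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    g = GenotypeMatrix(sample_ids, [f"snp{j + 1:05d}" for j in range(cfg.n_loci)],
                       calls)
    s = SampleTable(pd.DataFrame({
        "sample_id": sample_ids, "cluster": clusters, "site_id": sites,
    }))
    return g, s


def inject_missingness(g: GenotypeMatrix, rate: float,
                       seed: int) -> GenotypeMatrix:
    """Independently set each non-missing call to MISSING with prob ``rate``.

    The input matrix is not mutated.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = g.calls.copy()
    hit = (rng.random(calls.shape) < rate) & (calls != MISSING)
    calls[hit] = MISSING
    return GenotypeMatrix(list(g.sample_ids), list(g.locus_ids), calls)


#: Dominant congeners of the Aroclor 1254/1260 legacy fingerprint.
DEFAULT_DOMINANT_CONGENERS: tuple[int, ...] = (110, 153, 118, 138)

#: A realistic reporting set: the dominant four, the EU indicator six and a
#: spread of dioxin-like and minor congeners.
DEFAULT_CONGENER_SET: tuple[int, ...] = (
    28, 52, 66, 99, 101, 105, 110, 118, 126, 138, 153, 156, 170, 180, 187,
)


@dataclass
class ContaminantSimConfig:
    """Parameters of the log-normal contaminant simulator.

    One analyte per entry of ``analyte_baselines`` is generated, each with
    multiplicative species and region effects, a multiplicative per-year
    age effect on the log scale, and log-normal noise. ``detection_limit``
    applies per analyte (falling back to the shared default); PCB congener
    profiles are generated for each fish by splitting a simulated total PCB
    burden across ``congener_set``.
    """

    n_fish: int = 540
    # shared multiplicative species levels, dominated by the piscivorous
    # lake trout; calibrated so species means land in the ranges typical
    # of Arctic salmonid surveys (char Hg ~0.07 mg/kg ww, trout ~4x)
    species_effects: dict[str, float] = field(default_factory=lambda: {
        "Arctic char": 1.0, "lake trout": 4.0,
        "cisco": 1.1, "lake whitefish": 0.4,
    })
    region_effects: dict[int, float] = field(default_factory=lambda: {
        1: 1.0, 2: 1.4, 3: 0.9, 4: 0.8,
    })
    age_range: tuple[float, float] = (5.0, 30.0)
    age_slope: float = 0.05        # per-year, log scale
    sigma_log: float = 0.8
    detection_limit: float = 0.02
    congener_set: tuple[int, ...] = DEFAULT_CONGENER_SET
    dominant_congeners: tuple[int, ...] = DEFAULT_DOMINANT_CONGENERS
    analyte_baselines: dict[str, tuple[float, str]] = field(
        default_factory=lambda: {
            # analyte -> (young-char baseline concentration, basis)
            "Hg": (0.03, "ww"),   # mg/kg ww
            "As": (4.0, "dw"),    # mg/kg dw
            "Se": (1.0, "dw"),
        })
    total_pcb_baseline: float = 4.0  # ug/kg ww
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if not self.species_effects:
            raise ValueError("species_effects must not be empty")


def simulate_contaminants(cfg: ContaminantSimConfig) -> ContaminantTable:
    """Simulate a per-fish contaminant table with censored measurements.

    Species proportions lean towards the most-sampled species (the first
    entry of ``species_effects``); moisture and lipid fractions are drawn
    in species-typical ranges. Reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    species = list(cfg.species_effects)
    regions = list(cfg.region_effects)
    # first species twice as common as the rest, echoing a focal species
    w = np.array([2.0] + [1.0] * (len(species) - 1))
    sp = rng.choice(species, size=cfg.n_fish, p=w / w.sum())
    region = rng.choice(regions, size=cfg.n_fish)
    age = rng.uniform(*cfg.age_range, size=cfg.n_fish)

    fish = pd.DataFrame({
        "fish_id": [f"fish{i + 1:04d}" for i in range(cfg.n_fish)],
        "species": sp,
        "site_id": [f"g{r}_site" for r in region],
        "geographic_group": region,
        "age": age,
        "weight": np.round(rng.lognormal(np.log(1500), 0.6, cfg.n_fish), 1),
        "length": np.round(rng.normal(520, 90, cfg.n_fish), 1),
        "pct_lipid": rng.uniform(0.01, 0.12, cfg.n_fish),
        "pct_moisture": rng.uniform(0.68, 0.80, cfg.n_fish),
    })

    sp_eff = np.array([cfg.species_effects[s] for s in sp])
    rg_eff = np.array([cfg.region_effects[r] for r in region])

    def draw(baseline: float) -> np.ndarray:
        mu = (np.log(baseline) + np.log(sp_eff) + np.log(rg_eff)
              + cfg.age_slope * age)
        return np.exp(mu + rng.normal(0.0, cfg.sigma_log, cfg.n_fish))

    rows = []
    for analyte, (baseline, basis) in cfg.analyte_baselines.items():
        vals = draw(baseline)
        limit = cfg.detection_limit
        detected = vals > limit
        rows.append(pd.DataFrame({
            "fish_id": fish["fish_id"],
            "analyte": analyte,
            "value": np.where(detected, vals, limit),
            "basis": basis,
            "detected": detected,
            "detection_limit": limit,
        }))
    measurements = pd.concat(rows, ignore_index=True)

    # congener profiles: total burden split by Dirichlet weights with the
    # dominant set up-weighted ~8x
    total = draw(cfg.total_pcb_baseline)
    congeners = list(cfg.congener_set)
    alpha = np.array([8.0 if c in cfg.dominant_congeners else 1.0
                      for c in congeners])
    shares = rng.dirichlet(alpha, size=cfg.n_fish)
    conc = shares * total[:, None]
    climit = cfg.detection_limit
    crows = []
    for j, c in enumerate(congeners):
        detected = conc[:, j] > climit
        crows.append(pd.DataFrame({
            "fish_id": fish["fish_id"],
            "congener": c,
            "value": np.where(detected, conc[:, j], climit),
            "detected": detected,
            "detection_limit": climit,
        }))
    congener_df = pd.concat(crows, ignore_index=True)

    return ContaminantTable(fish=fish, measurements=measurements,
                            congeners=congener_df)
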