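"""Synthetic biparental DH trial generator.

Emulates the data structure of a maize doubled-haploid (DH) population
evaluated in testcross in multi-environment alpha-lattice trials with
repeated canopy hyperspectral measurements:

* DH genotypes from one meiosis of the F1, crossovers Poisson with no
  interference (Haldane model), then GBS-like noise (random missing calls
  and spurious heterozygous calls).
* A few-QTL additive genetic architecture whose in-sample variance is
  rescaled exactly to the configured genetic variance.
* Plot-level grain yield following the trial mixed model: overall mean +
  genotype + environment + GxE + replicate(environment) +
  block(replicate) + plot error, two replicates in incomplete blocks.
* Plot-level reflectance in 62 bands (392-850 nm) at five post-flowering
  flights, driven by a latent per-line-per-environment physiological
  score; bands above 700 nm carry more signal under drought stress and
  later flights are more informative.

Every stochastic step derives its own seed deterministically from the
single master seed in :class:`SimConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PARENT_A, PARENT_B, HET, MISSING

#: stage labels used to derive per-stage seeds from the master seed
_STAGES = ("genotypes", "noise", "qtl", "trials", "reflectance")

#: flight labels and their days after planting (metadata only)
FLIGHT_DAYS = {"F1": 55, "F2": 62, "F3": 69, "F4": 75, "F5": 83}


@dataclass
class GeneticMapSpec:
    """Chromosome lengths (cM) and ordered SNP positions per chromosome."""

    chromosomes: list  # list of (chrom_id, length_cM)
    snp_positions: dict  # chrom_id -> np.ndarray of cM positions

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("empty genetic map")
        total = 0.0
        for cid, length in self.chromosomes:
            if length < 0:
                raise ValueError(f"negative chromosome length for {cid}")
            pos = np.asarray(self.snp_positions.get(cid, ()), dtype=float)
            if pos.size and (np.any(pos < 0) or np.any(np.diff(pos) < 0)):
                raise ValueError(f"positions on {cid} must be sorted, non-negative")
            if pos.size and pos[-1] > length + 1e-9:
                raise ValueError(f"position beyond chromosome length on {cid}")
            self.snp_positions[cid] = pos
            total += length
        # a single 0-cM chromosome is legal (no recombination possible);
        # only a negative total is impossible
        if total < 0:
            raise ValueError("total map length must be non-negative")

    @property
    def n_snps(self) -> int:
        return int(sum(len(p) for p in self.snp_positions.values()))

    @property
    def total_length_cM(self) -> float:
        return float(sum(length for _, length in self.chromosomes))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, _ in self.chromosomes:
            for j, p in enumerate(self.snp_positions[cid]):
                rows.append((f"{cid}_S{j + 1}", cid, float(p)))
        return pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"])


def default_map(n_snps: int = 5000, n_chrom: int = 10,
                total_length_cM: float = 1150.16) -> GeneticMapSpec:
    """Ten equally long chromosomes with evenly spaced SNPs (~1150 cM total)."""
    if n_snps < n_chrom:
        raise ValueError("need at least one SNP per chromosome")
    length = total_length_cM / n_chrom
    base, extra = divmod(n_snps, n_chrom)
    chroms, positions = [], {}
    for c in range(n_chrom):
        cid = f"chr{c + 1}"
        m = base + (1 if c < extra else 0)
        chroms.append((cid, length))
        positions[cid] = np.linspace(0.0, length, m)
    return GeneticMapSpec(chroms, positions)


@dataclass
class TruthBundle:
    """Ground truth written by the generator, for recovery tests."""

    line_ids: list
    genetic_values: np.ndarray  # per line, trait units (Mg/ha)
    qtl: pd.DataFrame  # marker, chrom, pos_cM, effect
    env_ids: list = field(default_factory=list)
    env_effects: np.ndarray | None = None  # deviation from grand mean per env
    grand_mean: float = 0.0
    gxe_values: np.ndarray | None = None  # line x env, zero mean per env
    variance_components_true: dict = field(default_factory=dict)
    latent_physiology: np.ndarray | None = None  # line x env, unitless

    def to_dict(self) -> dict:
        out = {
            "line_ids": list(self.line_ids),
            "genetic_values": self.genetic_values.tolist(),
            "qtl": self.qtl.to_dict(orient="list"),
            "env_ids": list(self.env_ids),
            "grand_mean": self.grand_mean,
            "variance_components_true": dict(self.variance_components_true),
        }
        for key in ("env_effects", "gxe_values", "latent_physiology"):
            val = getattr(self, key)
            out[key] = None if val is None else np.asarray(val).tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TruthBundle":
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(
            line_ids=list(d["line_ids"]),
            genetic_values=np.asarray(d["genetic_values"], dtype=float),
            qtl=pd.DataFrame(d["qtl"]),
            env_ids=list(d["env_ids"]),
            env_effects=arr(d["env_effects"]),
            grand_mean=float(d["grand_mean"]),
            gxe_values=arr(d["gxe_values"]),
            variance_components_true=dict(d["variance_components_true"]),
            latent_physiology=arr(d["latent_physiology"]),
        )


@dataclass
class SimConfig:
    """Study-scale defaults: 97 DH lines, 4 environments (2 years x WW/DS),
    2 replicates in incomplete blocks of 10, 62 bands x 5 flights.

    Variance components are on the grain-yield plot scale (Mg/ha)^2; the
    plot-level heritability they imply is available as :meth:`h2_plot`.
    """

    n_lines: int = 97
    n_chrom: int = 10
    n_snps: int = 5000
    total_map_cM: float = 1150.16
    n_envs: int = 4
    n_reps: int = 2
    block_size: int = 10
    n_qtl: int = 5
    sigma_g2: float = 1.0
    gxe_ratio: float = 0.5  # sigma_GxE^2 / sigma_G^2
    sigma_rep2: float = 0.1
    sigma_block2: float = 0.1
    sigma_e2: float = 2.0
    missing_rate: float = 0.08
    het_error_rate: float = 0.025
    n_bands: int = 62
    n_flights: int = 5
    band_min_nm: float = 392.0
    band_max_nm: float = 850.0
    env_means: tuple = (5.7, 3.6, 5.9, 1.9)  # 14WW, 14DS, 16WW, 16DS (Mg/ha)
    alpha_geno: float = 0.7  # loading of standardized genetic value on latent s
    gamma_gxe: float = 0.5  # loading of standardized GxE on latent s
    latent_noise_sd: float = 0.5
    base_loading: float = 0.02  # reflectance units per latent s.d.
    stress_nir_factor: float = 1.6  # >700 nm loading multiplier in DS envs
    year_vis_tilt: float = 1.12  # visible-range loading gain in the early year
    year_nir_tilt: float = 1.15  # NIR loading gain in the late year
    ds_noise_factor: float = 2.0  # measurement-noise multiplier in DS envs
    meas_noise_sd: float = 0.025
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("missing_rate", "het_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_lines", "n_envs", "n_reps", "block_size", "n_bands",
                     "n_flights", "n_chrom", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        for name in ("sigma_g2", "gxe_ratio", "sigma_rep2", "sigma_block2",
                     "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.band_min_nm < self.band_max_nm):
            raise ValueError("band grid must have positive width")
        if len(self.env_means) != self.n_envs:
            raise ValueError("env_means length must equal n_envs")

    @property
    def sigma_gxe2(self) -> float:
        return self.sigma_g2 * self.gxe_ratio

    def h2_plot(self) -> float:
        """Plot-level heritability implied by the variance components."""
        tot = (self.sigma_g2 + self.sigma_gxe2 + self.sigma_rep2
               + self.sigma_block2 + self.sigma_e2)
        return self.sigma_g2 / tot

    def env_table(self) -> pd.DataFrame:
        """Environment labels: 2 years x WW/DS when n_envs == 4, else E1.."""
        if self.n_envs == 4:
            ids = ["14WW", "14DS", "16WW", "16DS"]
            years = [2014, 2014, 2016, 2016]
            treat = ["WW", "DS", "WW", "DS"]
        else:
            ids = [f"E{i + 1}" for i in range(self.n_envs)]
            years = [2014 + i for i in range(self.n_envs)]
            treat = ["WW" if i % 2 == 0 else "DS" for i in range(self.n_envs)]
        return pd.DataFrame(
            {"env": ids, "year": years, "treatment": treat,
             "mean": list(self.env_means)}
        )

    def band_wavelengths(self) -> np.ndarray:
        return np.linspace(self.band_min_nm, self.band_max_nm, self.n_bands)

    def band_columns(self) -> list:
        wl = np.round(self.band_wavelengths()).astype(int)
        if len(set(wl)) != len(wl):
            raise ValueError("band grid too dense for integer-nm labels")
        return [f"B{w}_F{t + 1}" for t in range(self.n_flights) for w in wl]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed (< 2^31) from the master seed."""
        if stage not in _STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STAGES.index(stage),))
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["env_means"] = list(d["env_means"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "env_means" in d:
            d["env_means"] = tuple(d["env_means"])
        return cls(**d)


# ---------------------------------------------------------------------------
# genotypes


def simulate_dh_genotypes(map_spec: GeneticMapSpec, n_lines: int,
                          seed: int) -> GenotypeMatrix:
    """Simulate fully homozygous DH lines from one biparental F1 meiosis.

    Each line is a single recombinant gamete, doubled: per chromosome the
    starting parental phase is a fair coin, crossover count is
    Poisson(length/100) and crossover positions are uniform (Haldane model,
    no interference). Calls are strictly parent-A / parent-B homozygous.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    for cid, length in map_spec.chromosomes:
        pos = map_spec.snp_positions[cid]
        m = len(pos)
        if m == 0:
            continue
        chrom_calls = np.empty((n_lines, m), dtype=np.int8)
        start_phase = rng.choice(np.array([PARENT_A, PARENT_B]), size=n_lines)
        n_xo = rng.poisson(length / 100.0, size=n_lines)
        for i in range(n_lines):
            if n_xo[i] == 0:
                chrom_calls[i] = start_phase[i]
                continue
            xo = np.sort(rng.uniform(0.0, length, size=n_xo[i]))
            flips = np.searchsorted(xo, pos, side="left")
            chrom_calls[i] = np.where(flips % 2 == 0, start_phase[i],
                                      -start_phase[i])
        blocks.append(chrom_calls)
    if not blocks:
        raise ValueError("map has no SNPs")
    calls = np.concatenate(blocks, axis=1)
    line_ids = [f"DH{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(calls, line_ids, map_spec.to_frame())


def apply_gbs_noise(geno: GenotypeMatrix, missing_rate: float,
                    het_error_rate: float, seed: int) -> GenotypeMatrix:
    """Inject GBS-style noise: each call is independently set to missing with
    ``missing_rate``, otherwise flipped to heterozygous with ``het_error_rate``."""
    for name, v in (("missing_rate", missing_rate),
                    ("het_error_rate", het_error_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed)
    u_miss = rng.random(geno.calls.shape)
    u_het = rng.random(geno.calls.shape)
    calls = geno.calls.copy()
    miss = u_miss < missing_rate
    het = ~miss & (u_het < het_error_rate)
    calls[miss] = MISSING
    calls[het] = HET
    return GenotypeMatrix(calls, list(geno.line_ids), geno.marker_map.copy())


def assign_qtl_effects(geno: GenotypeMatrix, n_qtl: int,
                       genetic_variance: float, seed: int) -> TruthBundle:
    """Sample additive QTL from the map and rescale their effects so the
    in-sample variance of the genetic values equals ``genetic_variance`` exactly.

    Must be called on noise-free DH genotypes (hom calls only).
    """
    if n_qtl > geno.n_snps:
        raise ValueError(f"n_qtl={n_qtl} exceeds {geno.n_snps} SNPs")
    if genetic_variance < 0:
        raise ValueError("genetic_variance must be >= 0")
    if np.any((geno.calls == HET) | (geno.calls == MISSING)):
        raise ValueError("QTL effects require noise-free homozygous genotypes")
    rng = np.random.default_rng(seed)
    if n_qtl == 0:
        return TruthBundle(
            line_ids=list(geno.line_ids),
            genetic_values=np.zeros(geno.n_lines),
            qtl=pd.DataFrame(columns=["marker", "chrom", "pos_cM", "effect"]),
        )
    idx = np.sort(rng.choice(geno.n_snps, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    g = geno.calls[:, idx].astype(float) @ effects
    sd = g.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate QTL draw: genetic values constant; "
                         "re-seed or increase n_qtl/n_lines")
    scale = math.sqrt(genetic_variance) / sd
    effects = effects * scale
    g = geno.calls[:, idx].astype(float) @ effects
    qtl = geno.marker_map.iloc[idx].copy().reset_index(drop=True)
    qtl["effect"] = effects
    return TruthBundle(
        line_ids=list(geno.line_ids),
        genetic_values=g,
        qtl=qtl,
    )


# ---------------------------------------------------------------------------
# trials


def simulate_trials(truth: TruthBundle, config: SimConfig) -> pd.DataFrame:
    """Simulate the multi-environment alpha-lattice trial (plot table).

    Plot value = grand mean + genotype + environment + GxE +
    replicate(env) + block(replicate) + plot error.  Genotypes are freshly
    randomized within each replicate and cut into consecutive incomplete
    blocks of ``block_size`` (last block padded short if needed).
    """
    n = len(truth.line_ids)
    if n != config.n_lines:
        raise ValueError("truth bundle and config disagree on n_lines")
    rng = np.random.default_rng(config.stage_seed("trials"))
    env_tab = config.env_table()
    u = float(np.mean(config.env_means))
    env_eff = np.asarray(config.env_means, dtype=float) - u

    gxe = rng.normal(0.0, math.sqrt(config.sigma_gxe2) if config.sigma_gxe2 else 0.0,
                     size=(n, config.n_envs))
    gxe -= gxe.mean(axis=0, keepdims=True)  # exactly zero mean per environment

    # cosmetic agronomic traits (line effect + noise); AD base differs by year
    ad_line = rng.normal(0.0, 1.5, size=n)
    ph_line = rng.normal(0.0, 10.0, size=n)

    rows = []
    plot_counter = 0
    for j, erow in env_tab.iterrows():
        stressed = erow["treatment"] == "DS"
        ad_base = 55.0 if erow["year"] == 2014 else 58.0
        asi_base = (1.6 if erow["year"] == 2014 else 3.1) if stressed else 0.8
        for rep in range(1, config.n_reps + 1):
            rep_eff = rng.normal(0.0, math.sqrt(config.sigma_rep2))
            perm = rng.permutation(n)
            n_blocks = math.ceil(n / config.block_size)
            block_eff = rng.normal(0.0, math.sqrt(config.sigma_block2),
                                   size=n_blocks)
            for slot, line_idx in enumerate(perm):
                b = slot // config.block_size
                eps = rng.normal(0.0, math.sqrt(config.sigma_e2))
                y = (u + truth.genetic_values[line_idx] + env_eff[j]
                     + gxe[line_idx, j] + rep_eff + block_eff[b] + eps)
                plot_counter += 1
                rows.append(
                    {
                        "env": erow["env"],
                        "year": int(erow["year"]),
                        "treatment": erow["treatment"],
                        "rep": rep,
                        "block": f"{erow['env']}_R{rep}_B{b + 1}",
                        "plot_id": f"P{plot_counter:05d}",
                        "genotype": truth.line_ids[line_idx],
                        "GY": y,
                        "AD": ad_base + ad_line[line_idx] + rng.normal(0, 1.0),
                        "SD": (ad_base + asi_base + ad_line[line_idx]
                               + rng.normal(0, 1.2)),
                        "PH": 200.0 + ph_line[line_idx] + rng.normal(0, 8.0),
                    }
                )
    truth.env_ids = env_tab["env"].tolist()
    truth.env_effects = env_eff
    truth.grand_mean = u
    truth.gxe_values = gxe
    truth.variance_components_true = {
        "sigma_g2": config.sigma_g2,
        "sigma_gxe2": config.sigma_gxe2,
        "sigma_rep2": config.sigma_rep2,
        "sigma_block2": config.sigma_block2,
        "sigma_e2": config.sigma_e2,
        "h2_plot": config.h2_plot(),
    }
    plots = pd.DataFrame(rows)
    if n % config.block_size:
        plots.attrs["padded_last_block"] = n % config.block_size
    return plots


# ---------------------------------------------------------------------------
# reflectance


def baseline_reflectance(wavelength_nm: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like baseline: dark visible range with a green bump,
    a red edge near 700-740 nm and a bright NIR plateau."""
    wl = np.asarray(wavelength_nm, dtype=float)
    green = 0.04 * np.exp(-0.5 * ((wl - 550.0) / 35.0) ** 2)
    red_edge = 0.40 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    return 0.05 + green + red_edge


def band_loadings(config: SimConfig, stressed: bool,
                  early_year: bool = True) -> np.ndarray:
    """Loadings w[b, t] of the latent physiological score on each band x flight.

    Later flights are more informative (gain grows linearly with flight
    index).  Above 700 nm the magnitude is multiplied by
    ``stress_nir_factor`` in stressed (DS) environments.  Informativeness
    also tilts by season: the early year reads more through the visible
    range, the late year through the NIR (mirroring the year-dependent
    repeatability pattern of real canopy spectra under differing stress
    severity).
    """
    wl = config.band_wavelengths()
    nir = wl > 700.0
    base = np.full(config.n_bands, config.base_loading)
    if early_year:
        base = np.where(nir, base / config.year_nir_tilt,
                        base * config.year_vis_tilt)
    else:
        base = np.where(nir, base * config.year_nir_tilt,
                        base / config.year_vis_tilt)
    if stressed:
        base = np.where(nir, base * config.stress_nir_factor, base)
    gains = 0.4 + 0.15 * np.arange(1, config.n_flights + 1)
    return np.outer(gains, base)  # (n_flights, n_bands)


def simulate_reflectance(truth: TruthBundle, config: SimConfig,
                         plots: pd.DataFrame) -> pd.DataFrame:
    """Append band x flight reflectance columns to the plot table.

    A latent physiological score per line x environment combines the
    standardized genetic value, the standardized GxE deviation and
    independent noise; each band reads ``baseline + w * s`` plus
    measurement noise.
    """
    if truth.gxe_values is None:
        raise ValueError("simulate_trials must run before simulate_reflectance")
    if config.n_bands < 1 or config.n_flights < 1:
        raise ValueError("n_bands and n_flights must be >= 1")
    rng = np.random.default_rng(config.stage_seed("reflectance"))
    n, n_env = truth.gxe_values.shape

    g = truth.genetic_values
    zg = (g - g.mean()) / g.std(ddof=0) if g.std() > 0 else np.zeros_like(g)
    zgxe = truth.gxe_values.copy()
    sd = zgxe.std(axis=0, ddof=0)
    nz = sd > 0
    zgxe[:, nz] = zgxe[:, nz] / sd[nz]

    s = (config.alpha_geno * zg[:, None] + config.gamma_gxe * zgxe
         + rng.normal(0.0, config.latent_noise_sd, size=(n, n_env)))
    truth.latent_physiology = s

    env_tab = config.env_table()
    base = baseline_reflectance(config.band_wavelengths())
    cols = config.band_columns()
    line_pos = {lid: i for i, lid in enumerate(truth.line_ids)}
    env_pos = {e: j for j, e in enumerate(env_tab["env"])}

    out = np.empty((len(plots), len(cols)))
    li = plots["genotype"].map(line_pos).to_numpy()
    ei = plots["env"].map(env_pos).to_numpy()
    median_year = float(env_tab["year"].median())
    for j, erow in env_tab.iterrows():
        stressed = erow["treatment"] == "DS"
        w = band_loadings(config, stressed=stressed,
                          early_year=erow["year"] <= median_year)
        mask = ei == j
        s_plot = s[li[mask], j]
        # flights stacked band-major within flight, matching band_columns()
        signal = np.hstack(
            [base[None, :] + np.outer(s_plot, w[t])
             for t in range(config.n_flights)]
        )
        noise_sd = config.meas_noise_sd * (config.ds_noise_factor
                                           if stressed else 1.0)
        out[mask] = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    bands = pd.DataFrame(out, columns=cols, index=plots.index)
    return pd.concat([plots, bands], axis=1)


def simulate_study(config: SimConfig):
    """Run the full generator: returns (clean genotypes, noisy genotypes,
    truth bundle, plot table with reflectance)."""
    map_spec = default_map(config.n_snps, config.n_chrom, config.total_map_cM)
    clean = simulate_dh_genotypes(map_spec, config.n_lines,
                                  config.stage_seed("genotypes"))
    noisy = apply_gbs_noise(clean, config.missing_rate, config.het_error_rate,
                            config.stage_seed("noise"))
    truth = assign_qtl_effects(clean, config.n_qtl, config.sigma_g2,
                               config.stage_seed("qtl"))
    plots = simulate_trials(truth, config)
    plots = simulate_reflectance(truth, config, plots)
    return clean, noisy, truth, plots
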