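"""Synthetic input tables with known ground truth.

Every generator is a pure function of a :class:`GeneratorConfig`: calling it
twice with the same config returns identical tables.  The five tables mirror
the field study design the pipeline expects:

* metabolic-rate observations (one fish, mass, SMR, MMR),
* intermittent-closed respirometry trials (per-cycle O2-decline slopes),
* field swimming-speed observations from stereo-video tracks,
* maximum-swimming-speed records (length, caudal aspect ratio, family x
  body-shape group),
* underwater visual-census records (site, transect, species, length, count),

plus a stereo-camera length-calibration set.

All metabolic rates are whole-animal g O2 d-1, masses g, lengths cm and
speeds cm s-1; regressions act on log10-transformed quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._exceptions import ConfigError

__all__ = [
    "SpeciesTruth",
    "GeneratorConfig",
    "default_species",
    "default_config",
    "recovery_config",
    "generate_mr_observations",
    "generate_respirometry_trials",
    "generate_speed_observations",
    "generate_maxspeed_records",
    "generate_census",
    "generate_calibration_set",
]

# fixed per-generator stream ids so tables are independent of call order
_STREAMS = {
    "mr": 11,
    "respirometry": 12,
    "speed": 13,
    "maxspeed": 14,
    "census": 15,
    "calibration": 16,
}


def _rng(config: "GeneratorConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground-truth trait and regression parameters for one species.

    ``a_*`` are log10 intercepts (value at 1 g or 1 cm), ``b_*`` the
    corresponding log10-log10 slopes.  ``lw_a``/``lw_b`` are the
    length-weight coefficients of W = lw_a * L**lw_b (g, cm).
    """

    species_id: str
    a_smr: float
    b_smr: float
    a_mmr: float
    b_mmr: float
    a_v: float
    b_v: float
    lw_a: float
    lw_b: float
    aspect_ratio: float
    family: str
    body_shape: str
    rest_hours: float = 12.0
    min_length_cm: int = 5
    max_length_cm: int = 30

    def __post_init__(self):
        if not (0.0 < self.b_smr < 1.5 and 0.0 < self.b_mmr < 1.5):
            raise ConfigError(
                f"{self.species_id}: mass-scaling exponents must lie in (0, 1.5)"
            )
        if self.a_mmr <= self.a_smr:
            raise ConfigError(
                f"{self.species_id}: MMR intercept must exceed SMR intercept"
            )
        if self.lw_a <= 0:
            raise ConfigError(f"{self.species_id}: lw_a must be positive")
        if not 0.0 <= self.rest_hours <= 24.0:
            raise ConfigError(f"{self.species_id}: rest_hours must lie in [0, 24]")
        if self.min_length_cm >= self.max_length_cm:
            raise ConfigError(f"{self.species_id}: degenerate length range")

    @property
    def group(self) -> str:
        """Family x body-shape group label used by the max-speed model."""
        return f"{self.family}|{self.body_shape}"


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with field-realistic defaults.

    Residual SDs are on the log10 scale.  ``rho_smr_mmr`` is the
    within-individual correlation of the SMR and MMR residuals (the
    covariation between the two rates for the same fish).
    """

    species: tuple[SpeciesTruth, ...]
    n_per_species: int = 10
    mass_range: tuple[float, float] = (5.0, 500.0)
    length_range: tuple[float, float] = (5.0, 30.0)
    sigma_mr: float = 0.05
    sigma_v: float = 0.37
    sigma_vmax: float = 0.10
    nu_v: float = 5.0
    nu_vmax: float = 5.0
    rho_smr_mmr: float = 0.5
    outlier_fraction: float = 0.0
    # respirometry trial shape
    n_cycles: int = 150
    cycle_minutes: float = 8.0
    sigma_cycle: float = 0.02
    activity_scale: float = 0.15
    floor_fraction: float = 0.15
    # max-speed regression truth (global parts; group offsets drawn once)
    a_vmax: float = 1.3
    b_vmax: float = 0.5
    c_ar: float = 0.05
    group_sd_vmax: float = 0.05
    n_maxspeed_per_group: int = 40
    ar_jitter_sd: float = 0.4  # within-group spread of caudal AR across species
    # census design
    sites: tuple[str, ...] = ("site_1", "site_2")
    n_transects: int = 3
    transect_area: float = 50.0
    fish_per_transect: int = 20
    rel_abundance: tuple[float, ...] | None = None
    # stereo-camera calibration truth
    error_intercept: float = 0.5
    error_slope: float = 0.1
    sigma_cal: float = 0.1
    distance_range: tuple[float, float] = (0.5, 8.0)
    n_calibration: int = 50
    seed: int = 0

    def __post_init__(self):
        if not self.species:
            raise ConfigError("species table must be non-empty")
        for name in ("sigma_v", "sigma_vmax", "sigma_cal", "sigma_mr", "sigma_cycle"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("mass_range", "length_range", "distance_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} is degenerate (min must be < max)")
        if self.nu_v <= 2 or self.nu_vmax <= 2:
            raise ConfigError("Student-t degrees of freedom must exceed 2")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ConfigError("outlier_fraction must lie in [0, 1)")
        if not -1.0 < self.rho_smr_mmr < 1.0:
            raise ConfigError("rho_smr_mmr must lie in (-1, 1)")
        if self.rel_abundance is not None:
            if len(self.rel_abundance) != len(self.species):
                raise ConfigError("rel_abundance length must match species")
            if abs(sum(self.rel_abundance) - 1.0) > 1e-9:
                raise ConfigError("rel_abundance must sum to 1")

    @property
    def species_map(self) -> dict[str, SpeciesTruth]:
        return {sp.species_id: sp for sp in self.species}


def default_species() -> tuple[SpeciesTruth, ...]:
    """Six reef-fish species with trait values typical of a coral reef
    assemblage (grouper-like piscivore through small grazing herbivores)."""
    mk = SpeciesTruth
    return (
        mk("Cephalopholis argus", math.log10(0.0033), 0.68, math.log10(0.0124),
           0.77, 0.55, 0.60, 0.0135, 3.05, 1.2, "Serranidae", "fusiform",
           min_length_cm=10, max_length_cm=45),
        mk("Chaetodon ornatissimus", math.log10(0.0038), 0.70, math.log10(0.0091),
           0.77, 0.75, 0.45, 0.0280, 3.00, 1.6, "Chaetodontidae", "compressed",
           min_length_cm=6, max_length_cm=18),
        mk("Ctenochaetus striatus", math.log10(0.0042), 0.76, math.log10(0.0103),
           0.77, 0.80, 0.42, 0.0230, 2.97, 2.2, "Acanthuridae", "compressed",
           min_length_cm=6, max_length_cm=22),
        mk("Naso lituratus", math.log10(0.0041), 0.73, math.log10(0.0146),
           0.78, 0.60, 0.62, 0.0200, 3.02, 2.9, "Acanthuridae", "fusiform",
           min_length_cm=10, max_length_cm=40),
        mk("Odonus niger", math.log10(0.0028), 0.70, math.log10(0.0129),
           0.77, 0.50, 0.70, 0.0260, 2.95, 3.1, "Balistidae", "compressed",
           min_length_cm=8, max_length_cm=35),
        mk("Zebrasoma scopas", math.log10(0.0038), 0.70, math.log10(0.0080),
           0.77, 0.85, 0.40, 0.0290, 2.98, 1.9, "Acanthuridae", "compressed",
           min_length_cm=5, max_length_cm=18),
    )


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(species=default_species(), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def recovery_config(
    seed: int = 0,
    b_global: float = 0.75,
    slope_offset_sd: float = 0.03,
    n_species: int = 6,
    n_per_species: int = 10,
    sigma_mr: float = 0.05,
    **overrides,
) -> GeneratorConfig:
    """Config for slope-recovery experiments: species mass-scaling exponents
    are ``b_global`` plus zero-mean offsets of SD ``slope_offset_sd``.

    The offsets are drawn from a dedicated stream of ``seed`` so the true
    global slope is exactly ``b_global`` by construction.
    """
    rng = np.random.default_rng([int(seed), 7])
    base = default_species()
    offsets = rng.normal(0.0, slope_offset_sd, size=(n_species, 2))
    offsets -= offsets.mean(axis=0)  # realized mean slope is exactly b_global
    species = []
    for i in range(n_species):
        proto = base[i % len(base)]
        species.append(
            replace(
                proto,
                species_id=f"sp_{i + 1}",
                b_smr=b_global + offsets[i, 0],
                b_mmr=b_global + offsets[i, 1],
            )
        )
    return GeneratorConfig(
        species=tuple(species),
        n_per_species=n_per_species,
        sigma_mr=sigma_mr,
        seed=seed,
        **overrides,
    )


def _log_uniform(rng, lo, hi, n):
    return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=n)


def generate_mr_observations(config: GeneratorConfig):
    """Draw per-fish masses and paired SMR/MMR values.

    Masses are log-uniform over ``mass_range``; log10 SMR and log10 MMR are
    normal around the species allometric lines with SD ``sigma_mr`` and
    within-fish residual correlation ``rho_smr_mmr``.

    Returns ``(observations, truth)`` where ``truth`` echoes the species
    table as a DataFrame.
    """
    rng = _rng(config, "mr")
    rho = config.rho_smr_mmr
    rows = []
    for sp in config.species:
        masses = _log_uniform(rng, *config.mass_range, config.n_per_species)
        e1 = rng.standard_normal(config.n_per_species)
        e2 = rng.standard_normal(config.n_per_species)
        e_mmr = rho * e1 + math.sqrt(1.0 - rho * rho) * e2
        logm = np.log10(masses)
        log_smr = sp.a_smr + sp.b_smr * logm + config.sigma_mr * e1
        log_mmr = sp.a_mmr + sp.b_mmr * logm + config.sigma_mr * e_mmr
        for i in range(config.n_per_species):
            rows.append(
                {
                    "individual_id": f"{sp.species_id}_{i + 1}",
                    "species_id": sp.species_id,
                    "mass_g": masses[i],
                    "smr": 10.0 ** log_smr[i],
                    "mmr": 10.0 ** max(log_mmr[i], log_smr[i]),
                }
            )
    obs = pd.DataFrame(rows)
    obs.attrs["seed"] = config.seed
    return obs, species_truth_frame(config)


def species_truth_frame(config: GeneratorConfig) -> pd.DataFrame:
    return pd.DataFrame([vars(sp) for sp in config.species])


def _chamber_volume(mass_g: float) -> float:
    """Chamber volume (L) scaled to fish size, in the 0.38-4.4 L range used
    for reef fish respirometry."""
    return float(min(4.4, max(0.38, 0.3 + 3.0 * mass_g / 1000.0)))


def generate_respirometry_trials(config: GeneratorConfig) -> list:
    """Build intermittent-closed respirometry trials.

    The first closed cycle carries the fish's true MMR (the post-chase
    measurement).  Later cycles are the true SMR multiplied by an activity
    elevation: a ``floor_fraction`` of cycles sit exactly on SMR (the resting
    lower envelope) and the rest are elevated by 10**Exponential(scale).
    Multiplicative log10-normal cycle noise ``sigma_cycle`` and, optionally,
    gross low outliers (0.02-0.1 x SMR, e.g. flush or probe failures) are
    applied on top.  Rates are converted to O2-decline slopes via the effective chamber
    volume (chamber minus fish volume at 1 g ml-1).
    """
    from .respirometry import RespirometryTrial  # local import avoids cycle

    if config.n_cycles < 12:
        raise ConfigError("n_cycles must be at least 12")
    rng = _rng(config, "respirometry")
    obs, _ = generate_mr_observations(config)
    trials = []
    n = config.n_cycles
    for row in obs.itertuples(index=False):
        smr, mmr = row.smr, row.mmr
        n_rest = n - 1
        elev = 10.0 ** rng.exponential(config.activity_scale, size=n_rest)
        n_floor = max(1, int(round(config.floor_fraction * n_rest)))
        floor_idx = rng.choice(n_rest, size=n_floor, replace=False)
        elev[floor_idx] = 1.0
        rates = smr * elev
        if config.sigma_cycle > 0:
            noise = 10.0 ** rng.normal(0.0, config.sigma_cycle, size=n_rest)
            rates = rates * noise
        outlier_idx = np.array([], dtype=int)
        if config.outlier_fraction > 0:
            n_out = int(round(config.outlier_fraction * n_rest))
            if n_out > 0:
                candidates = np.setdiff1d(np.arange(n_rest), floor_idx)
                outlier_idx = rng.choice(
                    candidates, size=min(n_out, candidates.size), replace=False
                )
                # sensor dropouts read a fraction of the resting rate no
                # matter how active the fish was that cycle
                rates[outlier_idx] = smr * rng.uniform(
                    0.02, 0.1, size=outlier_idx.size
                )
        all_rates = np.concatenate([[mmr], rates])
        volume = _chamber_volume(row.mass_g)
        eff = volume - row.mass_g / 1000.0
        if eff <= 0:
            raise ConfigError(
                f"{row.individual_id}: chamber volume does not exceed fish volume"
            )
        slopes = all_rates * 1000.0 / (eff * 1440.0)
        trials.append(
            RespirometryTrial(
                individual_id=row.individual_id,
                species_id=row.species_id,
                mass_g=row.mass_g,
                chamber_volume_l=volume,
                o2_slopes=slopes,
                cycle_minutes=np.full(n, config.cycle_minutes),
                true_smr=smr,
                true_mmr=mmr,
                outlier_cycles=tuple(sorted(int(i) + 1 for i in outlier_idx)),
            )
        )
    return trials


def generate_speed_observations(config: GeneratorConfig) -> pd.DataFrame:
    """Field swimming-speed observations: log10 speed is Student-t around
    the species speed-length line (heavy tails emulate tracking outliers).

    ``outlier_fraction`` additionally replaces that share of speeds with
    gross low values (factors 10**U(-2, -1)), emulating mis-tracked fish.
    """
    rng = _rng(config, "speed")
    rows = []
    for sp in config.species:
        lengths = _log_uniform(rng, *config.length_range, config.n_per_species)
        resid = config.sigma_v * rng.standard_t(config.nu_v, config.n_per_species)
        logv = sp.a_v + sp.b_v * np.log10(lengths) + resid
        if config.outlier_fraction > 0:
            n_out = int(round(config.outlier_fraction * config.n_per_species))
            if n_out > 0:
                idx = rng.choice(config.n_per_species, size=n_out, replace=False)
                logv[idx] = logv[idx] + rng.uniform(-2.0, -1.0, size=n_out)
        for i in range(config.n_per_species):
            rows.append(
                {
                    "individual_id": f"{sp.species_id}_v{i + 1}",
                    "species_id": sp.species_id,
                    "length_cm": lengths[i],
                    "v_field": 10.0 ** logv[i],
                    "n_segments": int(rng.integers(3, 6)),
                    "time_period": "08:00-10:00",
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["seed"] = config.seed
    return out


def maxspeed_group_offsets(config: GeneratorConfig) -> pd.DataFrame:
    """True intercept/slope offsets per family x body-shape group (drawn once
    from N(0, group_sd_vmax) on a dedicated stream of the seed)."""
    groups = sorted({sp.group for sp in config.species})
    rng = np.random.default_rng([int(config.seed), 8])
    offs = rng.normal(0.0, config.group_sd_vmax, size=(len(groups), 2))
    return pd.DataFrame(
        {"group": groups, "a_offset": offs[:, 0], "b_offset": offs[:, 1]}
    )


def generate_maxspeed_records(config: GeneratorConfig) -> pd.DataFrame:
    """Maximum-swim-speed records in the structure of a flume exhaustion
    study: per family x body-shape group, lengths plus caudal aspect ratio
    predict log10 vmax with Student-t noise."""
    groups = sorted({sp.group for sp in config.species})
    warn = None
    if len(groups) < 2:
        warn = "single family x body-shape group: group effects unidentifiable"
    offsets = maxspeed_group_offsets(config).set_index("group")
    ar_by_group: dict[str, list[float]] = {}
    for sp in config.species:
        ar_by_group.setdefault(sp.group, []).append(sp.aspect_ratio)
    rng = _rng(config, "maxspeed")
    rows = []
    for g in groups:
        fam, shape = g.split("|")
        lengths = _log_uniform(rng, *config.length_range, config.n_maxspeed_per_group)
        ars = rng.choice(ar_by_group[g], size=config.n_maxspeed_per_group)
        if config.ar_jitter_sd > 0:
            # a family holds many species with varying caudal fin shape
            ars = np.maximum(
                ars + rng.normal(0.0, config.ar_jitter_sd, size=ars.size), 0.3
            )
        resid = config.sigma_vmax * rng.standard_t(
            config.nu_vmax, config.n_maxspeed_per_group
        )
        logvm = (
            (config.a_vmax + offsets.loc[g, "a_offset"])
            + (config.b_vmax + offsets.loc[g, "b_offset"]) * np.log10(lengths)
            + config.c_ar * ars
            + resid
        )
        for i in range(config.n_maxspeed_per_group):
            rows.append(
                {
                    "record_id": f"{g}_{i + 1}",
                    "family": fam,
                    "body_shape": shape,
                    "length_cm": lengths[i],
                    "aspect_ratio": ars[i],
                    "v_max": 10.0 ** logvm[i],
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["seed"] = config.seed
    if warn:
        out.attrs["warning"] = warn
    return out


def generate_census(config: GeneratorConfig) -> pd.DataFrame:
    """Visual-census records: per site and transect, ``fish_per_transect``
    fish are allocated to species by a multinomial over the configured
    relative abundances (uniform by default) with integer-cm lengths uniform
    over each species' length range."""
    if not config.sites:
        raise ConfigError("site list must be non-empty")
    rng = _rng(config, "census")
    probs = (
        np.asarray(config.rel_abundance)
        if config.rel_abundance is not None
        else np.full(len(config.species), 1.0 / len(config.species))
    )
    rows = []
    for site in config.sites:
        for t in range(1, config.n_transects + 1):
            counts = rng.multinomial(config.fish_per_transect, probs)
            for sp, k in zip(config.species, counts):
                if k == 0:
                    continue
                lengths = rng.integers(sp.min_length_cm, sp.max_length_cm + 1, size=k)
                lens, lens_counts = np.unique(lengths, return_counts=True)
                for length, cnt in zip(lens, lens_counts):
                    rows.append(
                        {
                            "site": site,
                            "transect": f"{site}_T{t}",
                            "area_m2": config.transect_area,
                            "species_id": sp.species_id,
                            "total_length_cm": int(length),
                            "count": int(cnt),
                        }
                    )
    out = pd.DataFrame(rows)
    out.attrs["seed"] = config.seed
    return out


def generate_calibration_set(config: GeneratorConfig) -> pd.DataFrame:
    """Stereo-camera calibration pairs: measured length = true length +
    intercept + slope * distance + Normal(0, sigma_cal)."""
    rng = _rng(config, "calibration")
    true_len = rng.uniform(5.0, 40.0, size=config.n_calibration)
    dist = rng.uniform(*config.distance_range, size=config.n_calibration)
    measured = (
        true_len
        + config.error_intercept
        + config.error_slope * dist
        + rng.normal(0.0, config.sigma_cal, size=config.n_calibration)
    )
    out = pd.DataFrame(
        {
            "true_length_cm": true_len,
            "measured_length_cm": measured,
            "distance_m": dist,
        }
    )
    out.attrs["seed"] = config.seed
    return out
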