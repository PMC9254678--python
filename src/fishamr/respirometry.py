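"""Extraction of SMR and MMR from intermittent-closed respirometry trials.

A trial is a fish left ~24 h in a respirometry chamber after a chase to
exhaustion; each closed cycle yields an O2-decline slope.  The first cycle
(immediately post-chase) measures the maximum metabolic rate; the standard
metabolic rate is the mean of the lowest 10% of the remaining cycle rates
after robust outlier removal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import InputError

__all__ = [
    "RespirometryTrial",
    "mo2_from_cycle",
    "remove_outliers",
    "extract_smr",
    "extract_mmr",
    "summarize_trial",
    "summarize_trials",
]

log = logging.getLogger(__name__)


@dataclass
class RespirometryTrial:
    """One fish's intermittent-closed respirometry trial.

    ``o2_slopes`` are per-cycle O2-decline magnitudes (mg O2 L-1 min-1),
    ordered in time; cycle 1 is the post-chase MMR measurement.
    ``true_smr``/``true_mmr`` are optional ground-truth annotations carried
    by synthetic trials; ``outlier_cycles`` lists 0-based indices of
    injected gross outliers.
    """

    individual_id: str
    species_id: str
    mass_g: float
    chamber_volume_l: float
    o2_slopes: np.ndarray
    cycle_minutes: np.ndarray | None = None
    true_smr: float | None = None
    true_mmr: float | None = None
    outlier_cycles: tuple[int, ...] = ()

    def __post_init__(self):
        self.o2_slopes = np.asarray(self.o2_slopes, dtype=float)
        if self.o2_slopes.ndim != 1 or self.o2_slopes.size == 0:
            raise InputError(f"{self.individual_id}: empty trial")
        if np.any(self.o2_slopes < 0):
            raise InputError(
                f"{self.individual_id}: negative O2-decline slope after sign "
                "normalization"
            )
        if self.effective_volume_l <= 0:
            raise InputError(
                f"{self.individual_id}: chamber volume {self.chamber_volume_l} L "
                f"does not exceed fish volume {self.mass_g / 1000.0} L"
            )

    @property
    def effective_volume_l(self) -> float:
        """Water volume of the chamber: total minus the fish (1 g ml-1)."""
        return self.chamber_volume_l - self.mass_g / 1000.0

    @property
    def rates(self) -> np.ndarray:
        """Per-cycle whole-animal oxygen uptake rates (g O2 d-1)."""
        return mo2_from_cycle(self.o2_slopes, self.chamber_volume_l, self.mass_g)


def mo2_from_cycle(o2_slope, chamber_volume_l: float, mass_g: float):
    """Convert an O2-decline slope (mg O2 L-1 min-1) into a whole-animal
    uptake rate (g O2 d-1): slope x effective volume x 1440 / 1000.

    Accepts scalars or arrays of slopes.
    """
    eff = chamber_volume_l - mass_g / 1000.0
    if eff <= 0:
        raise InputError(
            f"effective volume non-positive ({chamber_volume_l} L chamber, "
            f"{mass_g} g fish)"
        )
    slope = np.asarray(o2_slope, dtype=float)
    if np.any(slope < 0):
        raise InputError("O2-decline slopes must be non-negative")
    rate = slope * eff * 1440.0 / 1000.0
    return float(rate) if np.isscalar(o2_slope) else rate


def remove_outliers(rates: np.ndarray, n_mad: float = 5.0) -> np.ndarray:
    """Boolean mask of rates kept by the median +/- n_mad * scaled-MAD rule.

    The rule runs on log10(rate) because cycle rates vary multiplicatively
    around the resting baseline, which makes gross low readings (the failure
    mode worth catching: flush or probe faults) detectable; the default
    threshold of 5 scaled MADs removes only order-of-magnitude departures
    and never trims the genuine resting tail of a trial.  Zero rates are
    always flagged.  If the MAD is zero (constant rates) nothing is removed.
    """
    rates = np.asarray(rates, dtype=float)
    keep = rates > 0
    if keep.sum() < 3:
        return keep
    lr = np.log10(rates[keep])
    med = np.median(lr)
    mad = 1.4826 * np.median(np.abs(lr - med))
    if mad > 0:
        ok = np.abs(lr - med) <= n_mad * mad
        keep[np.where(keep)[0][~ok]] = False
    return keep


def extract_smr(
    rates, lowest_fraction: float = 0.10, n_mad: float = 5.0
) -> float:
    """SMR = mean of the ``ceil(lowest_fraction * n)`` smallest rates after
    outlier removal.

    ``rates`` is the SMR pool (the MMR cycle must already be excluded by the
    caller; :func:`summarize_trial` does this).  Requires at least 10 rates.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 10:
        raise InputError(f"need >= 10 cycles in the SMR pool, got {rates.size}")
    if not 0.0 < lowest_fraction <= 1.0:
        raise InputError("lowest_fraction must lie in (0, 1]")
    kept = rates[remove_outliers(rates, n_mad=n_mad)]
    if kept.size == 0:
        raise InputError("outlier removal discarded every cycle")
    k = math.ceil(lowest_fraction * kept.size)
    return float(np.sort(kept)[:k].mean())


def extract_mmr(rates) -> float:
    """MMR = the rate of the first closed cycle (the post-chase measurement)."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise InputError("empty trial")
    return float(rates[0])


def summarize_trial(
    trial: RespirometryTrial,
    lowest_fraction: float = 0.10,
    n_mad: float = 5.0,
    exclude_first: bool = True,
) -> dict | None:
    """Reduce a trial to one (mass, SMR, MMR) observation.

    The first cycle is the MMR measurement and, by default, is excluded from
    the SMR pool.  Returns ``None`` (with a logged reason) when the trial
    violates SMR <= MMR, which indicates a failed MMR measurement rather
    than usable data.
    """
    rates = trial.rates
    pool = rates[1:] if exclude_first else rates
    if pool.size < 10:
        raise InputError(
            f"{trial.individual_id}: need >= 10 cycles after the MMR cycle, "
            f"got {pool.size}"
        )
    smr = extract_smr(pool, lowest_fraction=lowest_fraction, n_mad=n_mad)
    mmr = extract_mmr(rates)
    if smr > mmr:
        log.warning(
            "%s excluded: extracted SMR %.4g exceeds MMR %.4g",
            trial.individual_id, smr, mmr,
        )
        return None
    return {
        "individual_id": trial.individual_id,
        "species_id": trial.species_id,
        "mass_g": trial.mass_g,
        "smr": smr,
        "mmr": mmr,
    }


def summarize_trials(trials, **kwargs):
    """Summarize many trials into an MR-observation table.

    Returns ``(observations, excluded_ids)``; trials whose extracted
    SMR > MMR are dropped and listed.
    """
    rows, excluded = [], []
    for trial in trials:
        row = summarize_trial(trial, **kwargs)
        if row is None:
            excluded.append(trial.individual_id)
        else:
            rows.append(row)
    return pd.DataFrame(rows), excluded
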