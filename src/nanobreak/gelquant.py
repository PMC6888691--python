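"""Plasmid gel-electrophoresis quantification and its forward model.

A supercoiled plasmid relaxes to the open-circular form after one
single-strand break and linearizes after a double-strand break, so the
three gel bands (S supercoiled, R relaxed, L linear) quantify the damage
state of the population. The analysis chain is:

1. normalization with the staining factor f (default 1.47) correcting the
   weaker ethidium-bromide uptake of the supercoiled form::

       total = f·S + R + L,      L' = L / total

2. Poisson inversion to mean DSBs per plasmid: with per-plasmid break
   counts Poisson(μ) and at most one scoreable DSB per plasmid in the
   linear band, the observed linear fraction is L' = μ/(1+μ), hence::

       μ = L' / (1 − L')

3. an unweighted least-squares line of μ against dose; the slope m_DSB
   (breaks·plasmid⁻¹·Gy⁻¹) is the damage yield;

4. amplification factor AF = 100·(m_NP − m_control)/m_control and the
   hydroxyl-radical (scavenger) decomposition
   OH% = 100·(m − m_DMSO)/m.

The forward generator :func:`synth_gel` inverts the same chain exactly —
l = μ/(1+μ), supercoiled survival exp(−m_SSB·D) for the S band — and adds
truncated-Gaussian densitometry noise on the band intensities, so zero
noise round-trips to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_STAINING_FACTOR = 1.47


@dataclass(frozen=True)
class GelLane:
    """One densitometry lane: dose plus the three band intensities (a.u.)."""

    dose: float  # Gy
    S: float
    R: float
    L: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if min(self.S, self.R, self.L) < 0:
            raise ValueError("band intensities must be non-negative")
        if self.S == self.R == self.L == 0:
            raise ValueError("empty lane: all band intensities are zero")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class LaneFractions:
    total: float
    l_prime: float
    dsb_per_plasmid: float


@dataclass
class DoseResponse:
    """Fitted linear dose response of DSBs per plasmid."""

    doses: np.ndarray  # distinct doses, Gy
    mean_yields: np.ndarray  # mean breaks/plasmid per dose
    sd_yields: np.ndarray  # SD across replicates per dose
    slope: float  # breaks·plasmid⁻¹·Gy⁻¹
    slope_se: float
    intercept: float
    n_points: int


@dataclass
class AmplificationResult:
    """Yields and derived statistics of the four-arm scavenger experiment."""

    y_control: DoseResponse
    y_np: DoseResponse
    y_control_dmso: DoseResponse | None = None
    y_np_dmso: DoseResponse | None = None
    af: float = float("nan")
    af_se: float = float("nan")
    af_dmso: float = float("nan")
    af_dmso_se: float = float("nan")
    oh_effect_control: float = float("nan")
    oh_effect_control_se: float = float("nan")
    oh_effect_np: float = float("nan")
    oh_effect_np_se: float = float("nan")


def normalize_lane(
    lane: GelLane, staining_factor: float = DEFAULT_STAINING_FACTOR
) -> LaneFractions:
    """Normalize one lane and invert to DSBs per plasmid (steps 1–2)."""
    total = staining_factor * lane.S + lane.R + lane.L
    l_prime = lane.L / total
    if l_prime >= 1.0:
        raise ValueError(
            "all-linear lane (L' = 1): the Poisson inversion L'/(1-L') "
            "is out of domain"
        )
    return LaneFractions(
        total=total, l_prime=l_prime, dsb_per_plasmid=l_prime / (1.0 - l_prime)
    )


def fit_dose_response(
    lanes: list[GelLane], staining_factor: float = DEFAULT_STAINING_FACTOR
) -> DoseResponse:
    """Unweighted least-squares dose-response fit over all replicate lanes.

    All replicate points are pooled in the fit (intercept left free);
    per-dose mean and SD across replicates are retained for error bars.
    Requires at least three distinct doses.
    """
    if not lanes:
        raise ValueError("no lanes")
    doses = np.array([lane.dose for lane in lanes])
    yields = np.array(
        [normalize_lane(lane, staining_factor).dsb_per_plasmid for lane in lanes]
    )
    distinct = np.unique(doses)
    if len(distinct) < 3:
        raise ValueError(f"need >= 3 distinct doses, got {len(distinct)}")
    fit = stats.linregress(doses, yields)
    mean_yields = np.array([yields[doses == d].mean() for d in distinct])
    sd_yields = np.array(
        [yields[doses == d].std(ddof=1) if (doses == d).sum() > 1 else 0.0 for d in distinct]
    )
    return DoseResponse(
        doses=distinct,
        mean_yields=mean_yields,
        sd_yields=sd_yields,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
        n_points=len(lanes),
    )


def amplification(dr_np: DoseResponse, dr_control: DoseResponse) -> tuple[float, float]:
    """Amplification factor in percent with first-order SE propagation."""
    m0, m1 = dr_control.slope, dr_np.slope
    if m0 <= 0:
        raise ValueError("control slope must be positive")
    af = 100.0 * (m1 - m0) / m0
    se = 100.0 * np.hypot(dr_np.slope_se / m0, m1 * dr_control.slope_se / m0**2)
    return af, float(se)


def oh_effect(dr: DoseResponse, dr_dmso: DoseResponse) -> tuple[float, float]:
    """Fraction (percent) of the yield suppressed by the •OH scavenger."""
    m, m_s = dr.slope, dr_dmso.slope
    if m <= 0:
        raise ValueError("unscavenged slope must be positive")
    effect = 100.0 * (m - m_s) / m
    se = 100.0 * np.hypot(dr_dmso.slope_se / m, m_s * dr.slope_se / m**2)
    return effect, float(se)


def synth_gel(
    doses: list[float],
    m_dsb_true: float,
    m_ssb_true: float = 0.0,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    staining_factor: float = DEFAULT_STAINING_FACTOR,
) -> list[GelLane]:
    """Forward synthetic-gel generator (exact inverse of the analysis).

    Per dose D the true per-plasmid DSB mean is μ = m_dsb_true·D, giving a
    linear fraction l = μ/(1+μ); the surviving supercoiled fraction is
    s = (1−l)·exp(−m_ssb_true·D) and the relaxed remainder r = 1−l−s.
    Measured intensities are (s/staining_factor, r, l) plus independent
    Gaussian noise of SD ``noise_sd`` on each band, truncated at zero —
    densitometry noise lives on the band intensities, before
    normalization. Deterministic for a fixed seed.
    """
    if m_dsb_true < 0 or m_ssb_true < 0:
        raise ValueError("true yields must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    lanes: list[GelLane] = []
    for dose in doses:
        mu = m_dsb_true * dose
        l = mu / (1.0 + mu)
        if l >= 1.0:
            raise ValueError(f"linear fraction >= 1 at dose {dose}")
        s = (1.0 - l) * np.exp(-m_ssb_true * dose)
        r = 1.0 - l - s
        for rep in range(replicates):
            clean = np.array([s / staining_factor, r, l])
            bands = clean
            if noise_sd > 0:
                # redraw rather than emit an unmeasurable all-zero lane
                for _ in range(100):
                    bands = np.maximum(clean + rng.normal(0.0, noise_sd, size=3), 0.0)
                    if bands.any():
                        break
            lanes.append(
                GelLane(dose=dose, S=bands[0], R=bands[1], L=bands[2], replicate=rep)
            )
    return lanes


def lanes_to_frame(lanes: list[GelLane]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dose_Gy": [lane.dose for lane in lanes],
            "replicate": [lane.replicate for lane in lanes],
            "S": [lane.S for lane in lanes],
            "R": [lane.R for lane in lanes],
            "L": [lane.L for lane in lanes],
        }
    )


def write_lanes_csv(lanes: list[GelLane], path: str | Path) -> None:
    lanes_to_frame(lanes).to_csv(path, index=False)


def read_lanes_csv(path: str | Path) -> list[GelLane]:
    """Read lanes from CSV with columns dose_Gy, replicate, S, R, L."""
    frame = pd.read_csv(path)
    required = {"dose_Gy", "S", "R", "L"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in frame.columns:
        frame["replicate"] = 0
    return [
        GelLane(
            dose=float(row.dose_Gy),
            S=float(row.S),
            R=float(row.R),
            L=float(row.L),
            replicate=int(row.replicate),
        )
        for row in frame.itertuples()
    ]
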