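"""SSB/DSB scoring of a phase space on a duplex geometry.

The damage model is the standard direct-effect clustering rule:

* each energy deposit is assigned to the nearest sensitive site if it
  falls within that site's capture radius (otherwise discarded);
* a single-strand break (SSB) is called at every site whose accumulated
  energy strictly exceeds the energy threshold (default 8.22 eV, the
  effective ionization energy of the DNA molecule);
* a double-strand break (DSB) is a cluster of two or more SSBs involving
  both strands, where consecutive breaks (sorted along the duplex) are no
  more than the bp threshold apart (default 10 bp, inclusive). One cluster
  counts as one DSB regardless of how many SSBs it contains.

Yields are normalized to breaks per Gy per gigabase pair, and the
radio-enhancement amplification factor is the percentage increase of the
nanoparticle-loaded yield over the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from nanobreak.dnageom import DuplexGeometry
from nanobreak.tracks import PhaseSpace


@dataclass(frozen=True)
class DamageConfig:
    """Strand-break calling thresholds."""

    ssb_energy_threshold: float = 8.22  # eV, strict ">"
    dsb_bp_threshold: int = 10  # bp, inclusive "<="

    def __post_init__(self) -> None:
        if self.ssb_energy_threshold <= 0 or self.dsb_bp_threshold <= 0:
            raise ValueError("thresholds must be positive")


def accumulate(ps: PhaseSpace, duplex: DuplexGeometry) -> np.ndarray:
    """Per-site accumulated energy (eV), ordered like ``duplex`` sites.

    Each deposit goes to its nearest site when within the capture radius;
    no deposit is counted twice.
    """
    energies = np.zeros(len(duplex.strands))
    if len(ps) == 0:
        return energies
    tree = cKDTree(duplex.centers)
    dist, idx = tree.query(ps.positions)
    mask = dist <= duplex.capture_radius
    np.add.at(energies, idx[mask], ps.energies[mask])
    return energies


def call_ssb(
    site_energies: np.ndarray, duplex: DuplexGeometry, cfg: DamageConfig | None = None
) -> list[tuple[int, int]]:
    """SSBs as (strand, bp_index) pairs at sites strictly above threshold."""
    if cfg is None:
        cfg = DamageConfig()
    hits = np.flatnonzero(np.asarray(site_energies) > cfg.ssb_energy_threshold)
    ssbs = [(int(duplex.strands[i]), int(duplex.bp_indices[i])) for i in hits]
    return sorted(ssbs, key=lambda sb: (sb[1], sb[0]))


def call_dsb(
    ssbs: list[tuple[int, int]], cfg: DamageConfig | None = None
) -> list[list[tuple[int, int]]]:
    """Cluster SSBs into DSBs by a left-to-right sweep along the duplex.

    SSBs sorted by bp index are chained while the gap between consecutive
    breaks is <= the bp threshold (ties on opposite strands are gap 0);
    a closed cluster is a DSB iff it contains breaks on both strands.
    Each SSB belongs to at most one cluster, and one cluster scores as
    one DSB.
    """
    if cfg is None:
        cfg = DamageConfig()
    ordered = sorted(ssbs, key=lambda sb: (sb[1], sb[0]))
    clusters: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    for sb in ordered:
        if current and sb[1] - current[-1][1] > cfg.dsb_bp_threshold:
            clusters.append(current)
            current = []
        current.append(sb)
    if current:
        clusters.append(current)
    return [c for c in clusters if {s for s, _ in c} >= {0, 1}]


def dsb_rate(n_dsb: int, dose: float, length: float) -> float:
    """DSB yield in Gy⁻¹·Gbp⁻¹: ``n_dsb / dose / (length/1e9)``."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    return n_dsb / dose / (length / 1e9)


def amplification_factor(y_np: float, y_control: float) -> float:
    """Radio-enhancement in percent: ``100·(Y_NP − Y_control)/Y_control``."""
    if y_control <= 0:
        raise ValueError("control yield must be positive")
    return 100.0 * (y_np - y_control) / y_control


@dataclass
class DamageRecord:
    """Scored damage for one phase space on one duplex."""

    site_energy: np.ndarray
    ssbs: list[tuple[int, int]]
    dsbs: list[list[tuple[int, int]]] = field(default_factory=list)
    dose: float = 0.0  # Gy
    duplex_length: int = 0  # bp

    @property
    def n_ssb(self) -> int:
        return len(self.ssbs)

    @property
    def n_dsb(self) -> int:
        return len(self.dsbs)

    @property
    def rate(self) -> float:
        """DSB yield, Gy⁻¹·Gbp⁻¹ (0 when the record has no DSBs)."""
        if self.n_dsb == 0:
            return 0.0
        return dsb_rate(self.n_dsb, self.dose, self.duplex_length)

    def summary(self) -> dict:
        return {
            "n_ssb": self.n_ssb,
            "n_dsb": self.n_dsb,
            "dose_gy": self.dose,
            "duplex_length_bp": self.duplex_length,
            "dsb_rate_per_gy_per_gbp": self.rate,
        }


def score_damage(
    ps: PhaseSpace,
    duplex: DuplexGeometry,
    cfg: DamageConfig | None = None,
    dose: float | None = None,
) -> DamageRecord:
    """Full scoring chain: accumulate → call SSBs → cluster DSBs."""
    if cfg is None:
        cfg = DamageConfig()
    site_energy = accumulate(ps, duplex)
    ssbs = call_ssb(site_energy, duplex, cfg)
    dsbs = call_dsb(ssbs, cfg)
    return DamageRecord(
        site_energy=site_energy,
        ssbs=ssbs,
        dsbs=dsbs,
        dose=ps.target_dose if dose is None else dose,
        duplex_length=duplex.n_bp,
    )
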