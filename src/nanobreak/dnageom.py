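"""Sensitive-volume geometry of the scored biomolecule.

Strand-break scoring needs one spherical sensitive volume per
sugar-phosphate moiety, indexed by (strand, base-pair). Two sources are
supported:

* a procedural canonical B-DNA duplex (default): backbone sites on two
  helices with standard rise (0.34 nm) and twist (36°);
* a PDB file: one site per residue at the centroid of its backbone atoms,
  the first two chains mapping to strands 0 and 1 in file order. Nucleic
  chains use the P/O5'/C5'/C4'/C3'/O3' atoms; protein chains (used when a
  protein section stands in for the plasmid) use N/CA/C/O.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

NUCLEIC_BACKBONE = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
PROTEIN_BACKBONE = ("N", "CA", "C", "O")

#: default capture radius, nm (sugar-phosphate moiety scale)
DEFAULT_CAPTURE_RADIUS = 0.35


@dataclass(frozen=True)
class SensitiveSite:
    strand: int
    bp_index: int
    center: np.ndarray  # nm
    capture_radius: float  # nm


@dataclass
class DuplexGeometry:
    """Ordered (strand, base-pair) grid of sensitive-volume centres.

    Stored column-wise: ``strands``/``bp_indices`` are (2·n_bp,) integer
    arrays and ``centers`` the matching (2·n_bp, 3) nm coordinates, so
    nearest-site queries can go straight into a KD-tree.
    """

    strands: np.ndarray
    bp_indices: np.ndarray
    centers: np.ndarray
    capture_radius: float
    n_bp: int
    source: str = "procedural"

    def __post_init__(self) -> None:
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be positive")
        if len(self.strands) != 2 * self.n_bp:
            raise ValueError("expected exactly one site per (strand, bp_index)")

    @property
    def sites(self) -> list[SensitiveSite]:
        return [
            SensitiveSite(
                strand=int(self.strands[i]),
                bp_index=int(self.bp_indices[i]),
                center=self.centers[i],
                capture_radius=self.capture_radius,
            )
            for i in range(len(self.strands))
        ]

    def transformed(
        self, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)
    ) -> "DuplexGeometry":
        """Rigid-body copy: ``centers @ R.T + t``, indices unchanged."""
        centers = self.centers
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            centers = centers @ rotation.T
        centers = centers + np.asarray(translation, dtype=float)
        return DuplexGeometry(
            strands=self.strands.copy(),
            bp_indices=self.bp_indices.copy(),
            centers=centers,
            capture_radius=self.capture_radius,
            n_bp=self.n_bp,
            source=self.source,
        )


def build_bdna(
    n_bp: int,
    rise: float = 0.34,
    twist: float = 36.0,
    backbone_radius: float = 0.94,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
    origin=(0.0, 0.0, 0.0),
    strand_offset: float = 0.0,
) -> DuplexGeometry:
    """Procedural B-DNA backbone-site geometry.

    Site ``k`` of strand ``s`` sits at azimuth ``k·twist + s·(180° +
    strand_offset)`` on a helix of radius ``backbone_radius`` at height
    ``k·rise`` above ``origin``. Defaults are canonical B-DNA (0.34 nm
    rise, 36° twist ⇒ 10 bp per turn); ``strand_offset`` lets the second
    strand be rotated off the diameter to mimic the minor/major groove
    asymmetry.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    origin = np.asarray(origin, dtype=float)
    k = np.arange(n_bp)
    strands = np.repeat([0, 1], n_bp)
    bp_indices = np.concatenate([k, k])
    angles = np.deg2rad(
        np.concatenate([k * twist, k * twist + 180.0 + strand_offset])
    )
    centers = np.column_stack(
        [
            backbone_radius * np.cos(angles),
            backbone_radius * np.sin(angles),
            np.concatenate([k, k]) * rise,
        ]
    ) + origin
    return DuplexGeometry(
        strands=strands,
        bp_indices=bp_indices,
        centers=centers,
        capture_radius=capture_radius,
        n_bp=n_bp,
        source="procedural",
    )


def load_pdb(path: str | Path, capture_radius: float = DEFAULT_CAPTURE_RADIUS) -> DuplexGeometry:
    """Sensitive sites from a PDB structure (coordinates converted Å → nm).

    One site per residue at the centroid of its backbone atoms; the first
    two chains (file order) become strands 0 and 1, residue order within a
    chain gives the base-pair index. Files with more than two chains are
    accepted with a warning (extra chains dropped); fewer than two is an
    error since strand-break semantics need both strands. Chains of
    unequal length are truncated to the shorter.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models/records found")
    chains = list(models[0])
    if len(chains) < 2:
        raise ValueError(
            f"{path}: found {len(chains)} chain(s); two strands are required"
        )
    if len(chains) > 2:
        warnings.warn(
            f"{path}: {len(chains)} chains found; keeping the first two",
            stacklevel=2,
        )
        chains = chains[:2]

    per_chain: list[np.ndarray] = []
    for chain in chains:
        centroids = []
        for residue in chain:
            if residue.id[0] != " ":
                continue  # skip waters / heteroatoms
            names = {atom.get_name(): atom for atom in residue}
            backbone = [names[a] for a in NUCLEIC_BACKBONE if a in names]
            if not backbone:
                backbone = [names[a] for a in PROTEIN_BACKBONE if a in names]
            if not backbone:
                continue
            coords = np.stack([a.get_coord() for a in backbone]).astype(float)
            centroids.append(coords.mean(axis=0) / 10.0)  # Å → nm
        per_chain.append(np.array(centroids).reshape(-1, 3))
    if any(len(c) == 0 for c in per_chain):
        raise ValueError(f"{path}: a chain has no usable backbone atoms")
    n_bp = min(len(c) for c in per_chain)
    strands = np.repeat([0, 1], n_bp)
    bp_indices = np.concatenate([np.arange(n_bp), np.arange(n_bp)])
    centers = np.concatenate([per_chain[0][:n_bp], per_chain[1][:n_bp]])
    return DuplexGeometry(
        strands=strands,
        bp_indices=bp_indices,
        centers=centers,
        capture_radius=capture_radius,
        n_bp=n_bp,
        source=f"pdb:{path.stem}",
    )


def helix_pitch(rise: float = 0.34, twist: float = 36.0) -> float:
    """Helical pitch in nm (rise per full turn)."""
    if twist <= 0:
        raise ValueError("twist must be positive")
    return rise * 360.0 / twist


def interstrand_separation(backbone_radius: float = 0.94, strand_offset: float = 0.0) -> float:
    """Distance between paired backbone sites at the same bp, nm."""
    half_angle = math.radians(180.0 + strand_offset) / 2.0
    return 2.0 * backbone_radius * math.sin(half_angle)
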