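import numpy as np
import pytest

from nanobreak.gelquant import synth_gel
from nanobreak.npgeom import Phantom, build_phantom
from nanobreak.tracks import sample_events


def _pdb_atom(serial, name, resname, chain, resseq, xyz, element):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain:1s}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


#: per-residue backbone atoms of the fixture duplex, offsets in Å relative
#: to the residue anchor (names chosen so the nucleic backbone set matches)
_BACKBONE_OFFSETS = {
    "P": (0.0, 0.0, 0.0),
    "O5'": (1.0, 0.0, 0.0),
    "C5'": (1.0, 1.0, 0.0),
    "C4'": (0.0, 1.0, 1.0),
    "C3'": (0.0, 0.0, 2.0),
    "O3'": (1.0, 1.0, 2.0),
}

#: residue anchors in Å: two chains (strands) of two nucleotides each
FIXTURE_ANCHORS = {
    ("A", 1): (0.0, 0.0, 0.0),
    ("A", 2): (0.0, 0.0, 3.4),
    ("B", 1): (10.0, 0.0, 0.0),
    ("B", 2): (10.0, 0.0, 3.4),
}


def fixture_centroids_nm():
    """Hand-computable backbone centroids of the fixture PDB, in nm."""
    offsets = np.array(list(_BACKBONE_OFFSETS.values()))
    mean_offset = offsets.mean(axis=0)
    return {
        key: (np.array(anchor) + mean_offset) / 10.0
        for key, anchor in FIXTURE_ANCHORS.items()
    }


@pytest.fixture
def duplex_pdb(tmp_path):
    """Minimal synthetic two-chain, two-residue-per-chain PDB file."""
    path = tmp_path / "duplex_fixture.pdb"
    lines = []
    serial = 1
    for (chain, resseq), anchor in FIXTURE_ANCHORS.items():
        for name, off in _BACKBONE_OFFSETS.items():
            xyz = tuple(a + o for a, o in zip(anchor, off))
            lines.append(_pdb_atom(serial, name, "DA", chain, resseq, xyz, name[0]))
            serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


@pytest.fixture(scope="session")
def small_phantom():
    """A 12-particle phantom at the desk-scale study geometry."""
    volume = 4.0 / 3.0 * np.pi * 0.04**3  # r = 40 nm, µm³
    return build_phantom(
        n_particles=12,
        sphere_volume=volume,
        core_diameter=3.0,
        shell_thickness=2.0,
        shell_material="Pt",
        seed=11,
    )


@pytest.fixture(scope="session")
def empty_phantom():
    return Phantom(sphere_volume=0.5)


@pytest.fixture(scope="session")
def water_phase_space(empty_phantom):
    return sample_events(empty_phantom, target_dose=1.0, seed=3)


@pytest.fixture(scope="session")
def clean_gel_lanes():
    """Noiseless lanes at the published control yield."""
    return synth_gel(
        [0.0, 100.0, 200.0, 300.0, 400.0, 500.0],
        m_dsb_true=17.47e-5,
        m_ssb_true=2.0e-3,
        noise_sd=0.0,
        replicates=3,
        seed=0,
    )
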