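"""Shared fixtures: synthetic chain sets and a minimal PDB writer."""

from __future__ import annotations

import numpy as np
import pytest

from fcrnssp import ChainSet, ProteinChain, random_chain_set


@pytest.fixture(scope="session")
def small_chain_set() -> ChainSet:
    """Deterministic 16-chain synthetic dataset, 60 residues each."""
    return random_chain_set(16, length=60, seed=11)


@pytest.fixture(scope="session")
def toy_chains() -> ChainSet:
    return ChainSet(
        [
            ProteinChain("allH", "A" * 30, ss3="H" * 30),
            ProteinChain("mix", "ACD", ss3="HEC"),
            ProteinChain("coil", "GGGGGGGGGG", ss3="C" * 10),
        ]
    )


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    hetero: bool = False,
    altloc: str = " ",
    occupancy: float = 1.0,
) -> str:
    """Format one fixed-column ATOM/HETATM record."""
    record = "HETATM" if hetero else "ATOM  "
    # atom names shorter than 4 chars start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture()
def write_pdb(tmp_path):
    """Factory writing a list of atom-spec dicts to a temporary PDB file."""

    def _write(atom_specs, filename="toy.pdb"):
        lines = [
            pdb_atom_line(i + 1, **spec) for i, spec in enumerate(atom_specs)
        ]
        lines.append("END")
        path = tmp_path / filename
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
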