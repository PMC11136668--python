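import numpy as np
import pytest
from hypothesis import settings

import ligdyn as ld

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic 20-residue / 10-ligand-atom complex."""
    return ld.generate_complex(1, n_residues=20, n_ligand_atoms=10)


@pytest.fixture(scope="session")
def toy_trajectory(toy_complex):
    """50-frame trajectory with uniform sigma = 0.3 Å mobility."""
    profile = ld.MobilityProfile(sigma=np.full(toy_complex.n_atoms, 0.3))
    return ld.generate_trajectory(toy_complex, profile, n_frames=50, seed=2)


@pytest.fixture()
def rigid_alignment_trajectory(toy_complex):
    """Only the ligand moves; protein atoms are rigid so the per-frame
    superposition is exact (no noise-fitting bias)."""
    sigma = np.zeros(toy_complex.n_atoms)
    sigma[toy_complex.ligand_indices] = 0.5
    profile = ld.MobilityProfile(sigma=sigma)
    return ld.generate_trajectory(toy_complex, profile, n_frames=400, seed=7)


def make_fixed_frame_complex(coords, elements, n_protein):
    """Build a ComplexRecord directly from coordinates (test helper)."""
    atoms = []
    for i, (pos, el) in enumerate(zip(coords, elements)):
        role = "protein" if i < n_protein else "ligand"
        atoms.append(
            ld.AtomRecord(
                element=el,
                atom_name=f"{el}{i}",
                residue_index=i // 4 + 1 if role == "protein" else 999,
                residue_name="GLY" if role == "protein" else "LIG",
                chain_id="A",
                role=role,
                position=np.asarray(pos, dtype=float),
            )
        )
    return ld.ComplexRecord("TOYC", atoms)
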