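import numpy as np
import pytest

from ubfret import SimConfig, StateModel


@pytest.fixture
def three_state_model() -> StateModel:
    """K48-diUb 76C/0C three-state mixture (0.74/0.57/0.23 at 48/39/13%)."""
    return StateModel.diub_76c_0c()


@pytest.fixture
def burst_sample(three_state_model):
    """5,000 Gaussian-noise burst efficiencies from the three-state model."""
    from ubfret import gen_burst_efficiencies

    cfg = SimConfig(n_bursts=5000, seed=11, noise_model="gaussian")
    return gen_burst_efficiencies(three_state_model, cfg)["efficiency"].to_numpy()


def make_multimodel_pdb(path, models):
    """Write a minimal multi-MODEL PDB file.

    ``models`` is a list of atom lists; each atom is
    (chain, resnum, atomname, x, y, z).
    """
    lines = []
    for i, atoms in enumerate(models, start=1):
        lines.append(f"MODEL     {i:4d}")
        serial = 1
        for chain, resnum, name, x, y, z in atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} GLY {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
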