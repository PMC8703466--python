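import numpy as np
import pytest

from specbind.datamodel import TitrationPoint, TitrationSeries
from specbind.simulate import GroundTruth


@pytest.fixture
def truth():
    """Default ground truth: the study conditions."""
    return GroundTruth()


@pytest.fixture
def ligand_grid():
    """0-24 uM in 1 uM steps, the titration design."""
    return np.arange(25) * 1e-6


@pytest.fixture
def make_series():
    """Factory for a TitrationSeries from (ligand, F) arrays."""

    def _make(ligand, F, protein=4e-6, temperature=293.0, corrected=True, absorbances=None):
        pts = []
        for i, (l, f) in enumerate(zip(ligand, F)):
            a_ex = a_em = None
            if absorbances is not None:
                a_ex, a_em = absorbances[i]
            pts.append(TitrationPoint(float(l), float(f), a_ex, a_em))
        return TitrationSeries(
            protein_total=protein,
            temperature=temperature,
            points=tuple(pts),
            corrected=corrected,
        )

    return _make


@pytest.fixture
def titration_csv(tmp_path):
    """Write a titration CSV (uM units, two protein groups at 293 K)."""
    lines = ["# unit=uM", "protein_total,temperature,ligand_total,F_obs"]
    for prot in (6.0, 8.0):
        for lig in range(5):
            F = 1000.0 - 30.0 * lig * (6.0 / prot)
            lines.append(f"{prot},293,{lig},{F}")
    path = tmp_path / "titration.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
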