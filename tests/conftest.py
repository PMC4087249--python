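import numpy as np
import pytest

from suspect.conservation import MSA, MsaRow
from suspect.core import SAV, FeatureMatrix, Label
from suspect.synthfix import SynthSpec, gen_feature_dataset


@pytest.fixture
def toy_msa() -> MSA:
    """4-row alignment with strict E-value ordering.

    Query  : ACDEF
    hom1   : ACDEF (E=1e-30, identical)
    hom2   : ACGEF (E=1e-20, G at query position 3)
    hom3   : AC-EW (E=1e-10, gap at position 3, W at position 5)
    """
    return MSA(
        [
            MsaRow("query", "ACDEF", None),
            MsaRow("hom1", "ACDEF", 1e-30),
            MsaRow("hom2", "ACGEF", 1e-20),
            MsaRow("hom3", "AC-EW", 1e-10),
        ]
    )


@pytest.fixture
def small_dataset():
    """300-variant synthetic set with 9 planted informative features."""
    spec = SynthSpec(n_disease=150, n_neutral=150, effect_size=1.5, seed=42)
    matrix, labels = gen_feature_dataset(spec)
    return matrix, labels


@pytest.fixture
def simple_matrix():
    savs = [
        SAV("P1", 1, "A", "V", Label.DISEASE),
        SAV("P1", 2, "C", "G", Label.NEUTRAL),
        SAV("P2", 3, "D", "E", Label.DISEASE),
        SAV("P2", 4, "F", "Y", Label.NEUTRAL),
    ]
    values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
    return FeatureMatrix(savs, ["f_a", "f_b"], values, np.zeros_like(values, bool))
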