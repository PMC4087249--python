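"""Vendored amino-acid constant tables.

Only tables not shipped by an installed library live here: the Atchley
five-factor solution of the AAIndex physicochemical space, the BLOSUM62
background (marginal) amino-acid frequencies used as the default
conservation background, the side-chain charge convention, and the
aliphatic-index weights.  BLOSUM62 itself and the Kyte-Doolittle
hydropathy scale are taken from biopython (see `aa_props`).
"""

from __future__ import annotations

import numpy as np

#: Canonical one-letter alphabet, alphabetical. All 20xK arrays in the
#: package use this column order.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABET)}

# Atchley et al. (2005) five-factor summary of 494 AAIndex scales.
# Factor I: polarity/hydrophobicity, II: secondary structure propensity,
# III: molecular size, IV: codon composition, V: electrostatic charge.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

# BLOSUM62 marginal (background) amino-acid frequencies, the standard
# Robinson-Robinson-derived values used by PSI-BLAST. Renormalised to sum
# to exactly 1 in AA_ALPHABET order on module load.
_BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.0787945, "R": 0.0512953, "N": 0.0448725, "D": 0.0531767,
    "C": 0.0183006, "Q": 0.0342551, "E": 0.0632485, "G": 0.0695079,
    "H": 0.0224741, "I": 0.0573383, "L": 0.0934113, "K": 0.0641682,
    "M": 0.0235570, "F": 0.0407819, "P": 0.0492870, "S": 0.0722109,
    "T": 0.0574555, "W": 0.0131037, "Y": 0.0321647, "V": 0.0673004,
}


def blosum62_background() -> np.ndarray:
    """Background distribution over `AA_ALPHABET`, summing to 1."""
    v = np.array([_BLOSUM62_BACKGROUND[aa] for aa in AA_ALPHABET], dtype=float)
    return v / v.sum()


# Side-chain charge at physiological pH. Histidine is treated as neutral
# by default; pass ``his_charge`` to `charge_of` for the +0.5/+1 variants.
CHARGE: dict[str, int] = {aa: 0 for aa in AA_ALPHABET}
CHARGE.update({"D": -1, "E": -1, "K": 1, "R": 1})


def charge_of(aa: str, his_charge: float = 0.0) -> float:
    if aa == "H":
        return his_charge
    return float(CHARGE[aa])


# Aliphatic-index weights (Ikai 1980): AI = X_A + a*X_V + b*(X_I + X_L)
# with X the mole percentage of each residue.
ALIPHATIC_A: float = 2.9
ALIPHATIC_B: float = 3.9
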