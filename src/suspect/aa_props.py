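"""Amino-acid and whole-sequence physicochemical features.

Substitution-level features compare the wild-type and mutant residues
(BLOSUM62 score, charge change, glycine/proline involvement, Atchley
factor deltas); sequence-level indices (GRAVY, aliphatic index)
characterise the whole wild-type chain; annotation counts and predicted
solvent accessibility arrive as per-position tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from ._tables import (
    AA_ALPHABET,
    ALIPHATIC_A,
    ALIPHATIC_B,
    ATCHLEY_FACTORS,
    charge_of,
)
from .core import CANONICAL_AA, SAV, ProteinRecord
from .errors import BoundsError, ValidationError

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(wt: str, mut: str) -> int:
    """BLOSUM62 substitution score (symmetric)."""
    return int(_BLOSUM62[wt, mut])


def substitution_features(sav: SAV, his_charge: float = 0.0) -> dict:
    """Wild-type vs mutant residue comparison features.

    Returns the BLOSUM62 score, the charge change (mut - wt, with D/E at
    -1, K/R at +1 and His configurable), to/from glycine and proline
    flags, and the five Atchley factor deltas (mut - wt).
    """
    for aa in (sav.wt, sav.mut):
        if aa not in CANONICAL_AA:
            raise ValidationError(f"non-canonical residue {aa!r}")
    wt_f = np.array(ATCHLEY_FACTORS[sav.wt])
    mut_f = np.array(ATCHLEY_FACTORS[sav.mut])
    return {
        "blosum": blosum62(sav.wt, sav.mut),
        "charge_delta": charge_of(sav.mut, his_charge) - charge_of(sav.wt, his_charge),
        "to_gly": sav.mut == "G",
        "from_gly": sav.wt == "G",
        "to_pro": sav.mut == "P",
        "from_pro": sav.wt == "P",
        "atchley_delta": mut_f - wt_f,
    }


def aa_scale_delta(sav: SAV, scale: dict[str, float]) -> float:
    """Generic per-scale delta (mut - wt) for any aa -> value scale."""
    return float(scale[sav.mut]) - float(scale[sav.wt])


def _check_sequence(sequence: str, skip_noncanonical: bool) -> str:
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    bad = [c for c in seq if c not in CANONICAL_AA]
    if bad and not skip_noncanonical:
        raise ValidationError(f"non-canonical residues {sorted(set(bad))}")
    return "".join(c for c in seq if c in CANONICAL_AA) if bad else seq


def gravy(
    sequence: str,
    scale: dict[str, float] | None = None,
    skip_noncanonical: bool = False,
) -> float:
    """Grand average of hydropathy: mean per-residue hydropathy value
    (Kyte-Doolittle scale by default)."""
    seq = _check_sequence(sequence, skip_noncanonical)
    table = KYTE_DOOLITTLE if scale is None else scale
    return float(np.mean([table[c] for c in seq]))


def aliphatic_index(sequence: str, skip_noncanonical: bool = False) -> float:
    """Aliphatic index: X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu), with X
    the mole percentage of the residue; a thermostability correlate."""
    seq = _check_sequence(sequence, skip_noncanonical)
    n = len(seq)
    x = lambda aa: 100.0 * seq.count(aa) / n
    return x("A") + ALIPHATIC_A * x("V") + ALIPHATIC_B * (x("I") + x("L"))


def annotation_count(protein: ProteinRecord, position: int) -> int:
    """Number of functional annotations covering a position (``ft_count``
    track); 0 where the track has no entry."""
    val = protein.track_value("ft_count", position)
    return 0 if math.isnan(val) else int(val)


@lru_cache(maxsize=1)
def _codons_by_aa() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        table.setdefault(aa, []).append(codon)
    return table


def nssnp_reachable(wt: str, mut: str) -> bool:
    """Whether the substitution is reachable by a single nucleotide
    change under the standard genetic code."""
    codons = _codons_by_aa()
    for a in codons.get(wt, ()):
        for b in codons.get(mut, ()):
            if sum(x != y for x, y in zip(a, b)) == 1:
                return True
    return wt == mut  # trivially reachable by a synonymous change
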