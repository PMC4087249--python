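"""Sequence-conservation features from multiple sequence alignments and
position-specific scoring matrices.

Five of the nine default features come from here: the wild-type and
mutant PSSM scores and their difference, the Jensen-Shannon divergence of
the alignment column, and the percent identity to the first (lowest
E-value) homologue carrying the mutant residue.  The column gap fraction
and the E-value-ordered divergence features are also exposed.

Alignment conventions: the query is the first row; columns where the
query has a gap are insert columns and carry no query position, so they
are dropped from the position mapping (a PSSM has one row per query
residue only).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from ._tables import AA_ALPHABET, AA_INDEX, blosum62_background
from .core import SAV, logger
from .errors import BoundsError, FormatError, ParseError, ValidationError

GAP_CHARS = frozenset("-.")

#: E-value reported when no alignment row satisfies a divergence query;
#: the default PSI-BLAST inclusion ceiling.
SENTINEL_EVALUE = 10.0


@dataclass
class MsaRow:
    seq_id: str
    aligned: str
    evalue: float | None = None


@dataclass
class MSA:
    """A gapped alignment whose first row is the (query) sequence."""

    rows: list[MsaRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        width = len(self.rows[0].aligned)
        for r in self.rows:
            if len(r.aligned) != width:
                raise FormatError(
                    f"row {r.seq_id!r} has width {len(r.aligned)}, expected {width}"
                )
            if r.evalue is not None and r.evalue < 0:
                raise ValidationError(f"row {r.seq_id!r}: negative E-value")

    @property
    def query(self) -> MsaRow:
        return self.rows[0]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].aligned)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def query_columns(self) -> list[int]:
        """0-based column index of each query residue, insert columns dropped."""
        return [i for i, c in enumerate(self.query.aligned) if c not in GAP_CHARS]

    def column_for_position(self, position: int) -> int:
        """Alignment column (0-based) of a 1-based query position."""
        cols = self.query_columns()
        if not 1 <= position <= len(cols):
            raise BoundsError(f"query position {position} outside 1..{len(cols)}")
        return cols[position - 1]

    def column(self, index: int) -> str:
        if not 0 <= index < self.n_columns:
            raise BoundsError(f"column {index} outside 0..{self.n_columns - 1}")
        return "".join(r.aligned[index] for r in self.rows)


@dataclass
class PSSM:
    """Per-position log-odds scores, columns in `AA_ALPHABET` order."""

    scores: np.ndarray  # (positions, 20)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError("PSSM scores must be (positions, 20)")

    @property
    def positions(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, aa: str) -> float:
        if not 1 <= position <= self.positions:
            raise BoundsError(f"position {position} outside 1..{self.positions}")
        if aa not in AA_INDEX:
            raise ValidationError(f"non-canonical residue {aa!r}")
        return float(self.scores[position - 1, AA_INDEX[aa]])


_EVALUE_RE = re.compile(r"evalue=(\S+)")


def read_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA; an ``evalue=<x>`` header token is honoured."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ev = None
        m = _EVALUE_RE.search(rec.description)
        if m:
            ev = float(m.group(1))
        rows.append(MsaRow(rec.id, str(rec.seq).upper(), ev))
    if not rows:
        raise FormatError(f"{path}: no alignment records")
    return MSA(rows)


def read_psiblast_pssm(path: str | Path, query: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM.

    Expects the standard dialect: header lines, then one row per query
    position holding the index, the query residue, 20 integer log-odds and
    20 weighted-percentage columns (plus, in real PSI-BLAST output, two
    trailing information/weight fields). Only the log-odds block is kept.
    When ``query`` is given, the residue column and row count are checked
    against it.
    """
    col_order: str | None = None
    rows: list[tuple[str, list[float]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if col_order is None and len(tokens) >= 20 and all(
                len(t) == 1 and t.isalpha() for t in tokens
            ):
                col_order = "".join(tokens[:20]).upper()
                continue
            if not tokens[0].lstrip("-").isdigit():
                continue  # header/footer prose
            if len(tokens) < 2 or len(tokens[1]) != 1:
                continue
            residue = tokens[1].upper()
            try:
                nums = [float(t) for t in tokens[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if len(nums) not in (40, 42):
                raise ParseError(
                    f"{path}:{lineno}: expected 40 numeric fields "
                    f"(20 log-odds + 20 percentages), got {len(nums)}"
                )
            rows.append((residue, nums[:20]))
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    if col_order is None:
        col_order = "ARNDCQEGHILKMFPSTWYV"  # PSI-BLAST default order
    if sorted(col_order) != sorted(AA_ALPHABET):
        raise FormatError(f"{path}: unrecognised PSSM column alphabet {col_order!r}")
    perm = [col_order.index(aa) for aa in AA_ALPHABET]
    scores = np.array([[vals[j] for j in perm] for _, vals in rows], dtype=float)
    if query is not None:
        if len(rows) != len(query):
            raise FormatError(
                f"{path}: {len(rows)} PSSM rows but query length {len(query)}"
            )
        for i, (residue, _) in enumerate(rows):
            if query[i].upper() != residue:
                raise FormatError(
                    f"{path}: row {i + 1} residue {residue} != query {query[i]}"
                )
    return PSSM(scores)


def write_psiblast_pssm(pssm: PSSM, query: str, path: str | Path) -> None:
    """Write a PSSM in the ASCII dialect `read_psiblast_pssm` accepts
    (percentage columns are written as zeros)."""
    if len(query) != pssm.positions:
        raise ValidationError("query length != PSSM positions")
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("      " + "  ".join(AA_ALPHABET) + "  " + "  ".join(AA_ALPHABET) + "\n")
        for i in range(pssm.positions):
            scores = " ".join(f"{v:.2f}" for v in pssm.scores[i])
            zeros = " ".join("0" for _ in range(20))
            fh.write(f"{i + 1} {query[i]} {scores} {zeros}\n")


def pssm_features(pssm: PSSM, sav: SAV) -> dict[str, float]:
    """Wild-type score, mutant score and their difference at the SAV position."""
    wt = pssm.score(sav.position, sav.wt)
    mut = pssm.score(sav.position, sav.mut)
    return {"wt_score": wt, "mut_score": mut, "delta": wt - mut}


def compute_pssm_from_msa(
    msa: MSA, pseudocount: float = 1.0, background: np.ndarray | None = None
) -> PSSM:
    """Column log2-odds over a background; an internal PSSM stand-in.

    For each query-mapped column with amino-acid counts ``c`` over ``n``
    non-gap residues, score = log2(((c + pc*bg) / (n + pc)) / bg).
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    bg = blosum62_background() if background is None else np.asarray(background, float)
    cols = msa.query_columns()
    scores = np.zeros((len(cols), 20))
    for i, col in enumerate(cols):
        counts = np.zeros(20)
        for r in msa.rows:
            aa = r.aligned[col]
            if aa in AA_INDEX:
                counts[AA_INDEX[aa]] += 1
        n = counts.sum()
        freq = (counts + pseudocount * bg) / (n + pseudocount)
        scores[i] = np.log2(freq / bg)
    return PSSM(scores)


def gap_fraction(msa: MSA, column: int) -> float:
    """Proportion of gap characters in an alignment column."""
    col = msa.column(column)
    return sum(c in GAP_CHARS for c in col) / len(col)


def column_distribution(msa: MSA, column: int) -> np.ndarray:
    """Amino-acid distribution of a column, gaps and non-canonicals excluded."""
    counts = np.zeros(20)
    for c in msa.column(column):
        if c in AA_INDEX:
            counts[AA_INDEX[c]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def js_divergence(
    msa: MSA,
    column: int,
    lam: float = 0.5,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.999,
) -> float | None:
    """Jensen-Shannon divergence (bits) of a column against a background.

    With P the column distribution, Q the background and M = lam*P +
    (1-lam)*Q: JSD = lam*KL(P||M) + (1-lam)*KL(Q||M), base-2 logs, so the
    value lies in [0, 1]. Columns at or above ``max_gap_fraction`` gaps
    are excluded and return None.
    """
    if not 0 < lam < 1:
        raise ValidationError("lambda must be in (0, 1)")
    if gap_fraction(msa, column) >= max_gap_fraction:
        return None
    p = column_distribution(msa, column)
    q = blosum62_background() if background is None else np.asarray(background, float)
    if not math.isclose(float(q.sum()), 1.0, rel_tol=1e-6):
        raise ValidationError("background must sum to 1")
    if p.sum() == 0:
        return None  # no residues at all in an includable column
    m = lam * p + (1 - lam) * q
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log2(p / m), 0.0).sum()
        kl_qm = np.where(q > 0, q * np.log2(q / m), 0.0).sum()
    return float(lam * kl_pm + (1 - lam) * kl_qm)


def percent_identity(
    msa: MSA, row_index: int, over_query_length: bool = False
) -> float:
    """Percent identity of a row to the query.

    By default computed over columns where both query and subject are
    non-gap; ``over_query_length`` divides by the number of query residue
    columns instead.
    """
    q = msa.query.aligned
    s = msa.rows[row_index].aligned
    matches = 0
    both = 0
    for a, b in zip(q, s):
        if a in GAP_CHARS:
            continue
        if b not in GAP_CHARS:
            both += 1
            if a == b:
                matches += 1
    denom = len(msa.query_columns()) if over_query_length else both
    return 100.0 * matches / denom if denom else 0.0


def divergence_features(
    msa: MSA,
    sav: SAV,
    sentinel_evalue: float = SENTINEL_EVALUE,
    identity_over_query_length: bool = False,
) -> dict[str, float]:
    """E-value/identity of the best rows diverging at the SAV position.

    Non-query rows are scanned in ascending E-value order (rows without an
    E-value last, original order preserved). The first row whose residue
    at the SAV column is (i) neither gap nor wild type, and (ii) exactly
    the mutant, contribute their E-value and percent identity to the
    query. When no qualifying row exists the E-value falls back to
    ``sentinel_evalue`` and the identity to 0.
    """
    col = msa.column_for_position(sav.position)
    if msa.query.aligned[col] in GAP_CHARS:
        raise ValidationError("SAV position maps to a query gap column")
    order = sorted(
        range(1, msa.n_rows),
        key=lambda i: (msa.rows[i].evalue is None, msa.rows[i].evalue or 0.0, i),
    )
    out = {
        "first_nonwt_evalue": sentinel_evalue,
        "first_nonwt_identity": 0.0,
        "first_mut_evalue": sentinel_evalue,
        "first_mut_identity": 0.0,
    }
    found_nonwt = found_mut = False
    for i in order:
        aa = msa.rows[i].aligned[col]
        if aa in GAP_CHARS:
            continue
        ev = msa.rows[i].evalue
        ident = percent_identity(msa, i, identity_over_query_length)
        if not found_nonwt and aa != sav.wt:
            out["first_nonwt_evalue"] = ev if ev is not None else sentinel_evalue
            out["first_nonwt_identity"] = ident
            found_nonwt = True
        if not found_mut and aa == sav.mut:
            out["first_mut_evalue"] = ev if ev is not None else sentinel_evalue
            out["first_mut_identity"] = ident
            found_mut = True
        if found_nonwt and found_mut:
            break
    return out


def read_emissions(path: str | Path) -> dict[int, dict[str, float]]:
    """Read per-position HMM emission probabilities.

    TSV rows: 1-based position then 20 probabilities in `AA_ALPHABET`
    order. Positions absent from the file are outside any domain.
    """
    table: dict[int, dict[str, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) != 21:
                raise ParseError(
                    f"{path}:{lineno}: expected position + 20 probabilities"
                )
            pos = int(tokens[0])
            vals = [float(t) for t in tokens[1:]]
            table[pos] = dict(zip(AA_ALPHABET, vals))
    return table


def pfam_emission_delta(
    emissions: Mapping[int, Mapping[str, float]] | None, sav: SAV
) -> float:
    """Wild-type minus mutant domain-HMM emission probability.

    NaN (missing) when the position lies outside every domain, i.e. has
    no emission entry.
    """
    if emissions is None or sav.position not in emissions:
        return math.nan
    probs = emissions[sav.position]
    wt, mut = probs[sav.wt], probs[sav.mut]
    for v in (wt, mut):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"emission probability {v} outside [0, 1]")
    return wt - mut
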