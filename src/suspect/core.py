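"""Domain types and plain-text I/O shared by every stage.

The unit of prediction is the single amino acid variant (SAV): one
substitution at a 1-based position of a protein. Per-position evidence
from external tools (predicted relative solvent accessibility, disorder,
annotation counts, ...) attaches to a `ProteinRecord` as named numeric
"tracks"; per-SAV features assemble into a `FeatureMatrix`.

Positions are 1-based everywhere in the public API; conversion to 0-based
array indices happens at the boundary, inside each accessor.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from ._tables import AA_ALPHABET
from .errors import (
    BoundsError,
    ConsistencyError,
    FormatError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger("suspect")

CANONICAL_AA = frozenset(AA_ALPHABET)


class Label(str, Enum):
    """Phenotype annotation of a variant."""

    DISEASE = "disease"
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Label":
        t = text.strip().lower()
        if t in ("disease", "pathogenic", "deleterious"):
            return cls.DISEASE
        if t in ("neutral", "polymorphism", "benign", "tolerated"):
            return cls.NEUTRAL
        # anything else (e.g. "unclassified") is excluded from training
        return cls.UNKNOWN


@dataclass(frozen=True)
class SAV:
    """One candidate substitution: ``wt`` at 1-based ``position`` -> ``mut``."""

    protein_id: str
    position: int
    wt: str
    mut: str
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )
        for name, aa in (("wt", self.wt), ("mut", self.mut)):
            if aa not in CANONICAL_AA:
                raise ValidationError(
                    f"{self.protein_id} position {self.position}: "
                    f"{name} residue {aa!r} is not one of the 20 canonical amino acids"
                )
        if self.wt == self.mut:
            raise ValidationError(
                f"{self.protein_id} position {self.position}: wt == mut ({self.wt})"
            )

    def __str__(self) -> str:  # p.C873G style, compact
        return f"{self.protein_id}:{self.wt}{self.position}{self.mut}"


@dataclass
class ProteinRecord:
    """A protein sequence plus named per-position numeric tracks.

    Track vectors are float arrays of the sequence length with NaN for
    positions the track does not cover.
    """

    protein_id: str
    sequence: str
    tracks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"{self.protein_id}: empty sequence")
        self.sequence = self.sequence.upper()
        for name, vec in self.tracks.items():
            if len(vec) != len(self.sequence):
                raise ValidationError(
                    f"{self.protein_id}: track {name!r} length {len(vec)} "
                    f"!= sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise BoundsError(
                f"{self.protein_id}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]

    def track_value(self, name: str, position: int) -> float:
        """Track value at a 1-based position; NaN when absent."""
        if not 1 <= position <= len(self.sequence):
            raise BoundsError(
                f"{self.protein_id}: position {position} outside 1..{len(self.sequence)}"
            )
        if name not in self.tracks:
            return math.nan
        return float(self.tracks[name][position - 1])


@dataclass
class FeatureMatrix:
    """Dense per-SAV feature vectors with an explicit missingness mask.

    ``values[i, j]`` is finite wherever ``missing_mask[i, j]`` is False;
    masked entries may hold anything (NaN by convention).
    """

    savs: list[SAV]
    feature_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if n != len(self.savs):
            raise ValidationError(f"{n} rows but {len(self.savs)} SAVs")
        if p != len(self.feature_names):
            raise ValidationError(f"{p} columns but {len(self.feature_names)} names")
        if len(set(self.feature_names)) != p:
            raise ValidationError("feature names must be unique")
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError("missing_mask shape mismatch")
        bad = ~np.isfinite(self.values) & ~self.missing_mask
        if bad.any():
            raise ValidationError("non-finite value not covered by missing_mask")

    @classmethod
    def from_columns(
        cls, savs: Sequence[SAV], columns: Mapping[str, Sequence[float]]
    ) -> "FeatureMatrix":
        """Build from named columns; NaN entries become masked-missing."""
        names = list(columns)
        if names:
            values = np.column_stack([np.asarray(columns[c], float) for c in names])
        else:
            values = np.empty((len(savs), 0))
        mask = ~np.isfinite(values)
        return cls(list(savs), names, values, mask)

    @property
    def n_savs(self) -> int:
        return len(self.savs)

    @property
    def labels(self) -> np.ndarray:
        """Binary labels (1 = disease, 0 = neutral, -1 = unknown)."""
        code = {Label.DISEASE: 1, Label.NEUTRAL: 0, Label.UNKNOWN: -1}
        return np.array([code[s.label] for s in self.savs], dtype=int)

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            from .errors import SchemaError

            raise SchemaError(f"unknown features requested: {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            self.savs, list(names), self.values[:, idx], self.missing_mask[:, idx]
        )

    def select_rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            [self.savs[i] for i in idx],
            list(self.feature_names),
            self.values[idx],
            self.missing_mask[idx],
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            np.where(self.missing_mask, np.nan, self.values),
            columns=self.feature_names,
        )
        df.insert(0, "protein_id", [s.protein_id for s in self.savs])
        df.insert(1, "position", [s.position for s in self.savs])
        df.insert(2, "wt", [s.wt for s in self.savs])
        df.insert(3, "mut", [s.mut for s in self.savs])
        df.insert(4, "label", [s.label.value for s in self.savs])
        return df


@dataclass
class SvmConfig:
    C: float = 128.0
    gamma: float = 0.01

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValidationError("C and gamma must be positive")


@dataclass
class SelectionConfig:
    n_subsets: int = 100
    subsample_fraction: float = 0.5
    alpha: float = 0.5
    k_per_iteration: int = 30
    keep_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValidationError("n_subsets must be >= 1")
        if not 0 < self.subsample_fraction < 1:
            raise ValidationError("subsample_fraction must be in (0, 1)")
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must be in [0, 1]")
        if self.k_per_iteration < 1:
            raise ValidationError("k_per_iteration must be >= 1")
        if not 0 < self.keep_threshold <= 1:
            raise ValidationError("keep_threshold must be in (0, 1]")


@dataclass
class RunConfig:
    """Run-wide configuration with the published defaults."""

    seed: int = 0
    svm: SvmConfig = field(default_factory=SvmConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    score_cutoff: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.score_cutoff <= 100:
            raise ValidationError("score_cutoff must be in [0, 100]")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            seed=int(raw.get("seed", 0)),
            svm=SvmConfig(**raw.get("svm", {})),
            selection=SelectionConfig(**raw.get("selection", {})),
            score_cutoff=float(raw.get("score_cutoff", 50.0)),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# I/O


def parse_variant_table(
    path: str | Path, proteins: Mapping[str, ProteinRecord] | None = None
) -> list[SAV]:
    """Read a variant TSV: protein_id, 1-based position, wt, mut[, label].

    Rows come back in file order. When ``proteins`` is given, each SAV's
    wild-type residue is checked against the corresponding sequence.
    """
    savs: list[SAV] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 4 tab-separated fields, got {len(row)}"
                )
            pid = row[0].strip()
            try:
                pos = int(row[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer position {row[1]!r}") from exc
            label = Label.parse(row[4]) if len(row) > 4 and row[4].strip() else Label.UNKNOWN
            try:
                sav = SAV(pid, pos, row[2].strip().upper(), row[3].strip().upper(), label)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if proteins is not None and pid in proteins:
                rec = proteins[pid]
                actual = rec.residue(sav.position)
                if actual != sav.wt:
                    raise ConsistencyError(
                        f"{pid} position {sav.position}: variant wild-type {sav.wt} "
                        f"but sequence has {actual}"
                    )
            savs.append(sav)
    return savs


def write_variant_table(savs: Iterable[SAV], path: str | Path) -> None:
    """Inverse of `parse_variant_table` (labels always written)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in savs:
            writer.writerow([s.protein_id, s.position, s.wt, s.mut, s.label.value])


def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read protein sequences; the first header token is the protein id."""
    records: dict[str, ProteinRecord] = {}
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FormatError(f"{path}: no FASTA records")
    for rec in parsed:
        pid = rec.id
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {pid!r} has an empty sequence")
        if pid in records:
            raise FormatError(f"{path}: duplicate protein id {pid!r}")
        records[pid] = ProteinRecord(pid, seq)
    return records


def read_track(path: str | Path, protein: ProteinRecord, name: str) -> ProteinRecord:
    """Attach a per-position track from a TSV of ``position<TAB>value`` rows.

    Positions absent from the file stay NaN (missing). Returns the same
    record, mutated in place, for chaining.
    """
    vec = np.full(len(protein.sequence), np.nan)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected position<TAB>value")
            try:
                pos = int(row[0])
                val = float(row[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if not 1 <= pos <= len(protein.sequence):
                raise BoundsError(
                    f"{path}:{lineno}: position {pos} outside 1..{len(protein.sequence)} "
                    f"for protein {protein.protein_id}"
                )
            vec[pos - 1] = val
    protein.tracks[name] = vec
    return protein


def feature_matrix_from_dataframe(df) -> FeatureMatrix:
    """Rebuild a FeatureMatrix from the tidy frame layout produced by
    `FeatureMatrix.to_dataframe` (meta columns + numeric feature columns)."""
    meta = {"protein_id", "position", "wt", "mut", "label"}
    feature_cols = [c for c in df.columns if c not in meta]
    savs = [
        SAV(
            str(r.protein_id),
            int(r.position),
            str(r.wt),
            str(r.mut),
            Label.parse(str(getattr(r, "label", "unknown"))),
        )
        for r in df.itertuples(index=False)
    ]
    return FeatureMatrix.from_columns(
        savs, {c: np.asarray(df[c], dtype=float) for c in feature_cols}
    )


def child_seed(seed: int, *salt: int) -> int:
    """Deterministic child seed below 2**31, stable across platforms."""
    ss = np.random.SeedSequence([int(seed), *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))
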