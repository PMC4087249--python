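"""Orchestration: assemble per-variant feature matrices, cross-validate,
and summarise structural coverage.

The default feature plan emits the nine-column signature that feature
selection retains on the full training design: PPI degree centrality,
the per-position annotation count, the three PSSM scores, the domain-HMM
emission difference, the Jensen-Shannon column divergence, the percent
identity of the first homologue carrying the mutant residue, and the
predicted relative solvent accessibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import aa_props, conservation, netfeat
from .conservation import MSA, PSSM
from .core import (
    SAV,
    FeatureMatrix,
    ProteinRecord,
    RunConfig,
    child_seed,
    logger,
)
from .errors import ConfigError, DegenerateInputError, ValidationError
from .evalstats import EvalReport
from .learner import predict_score, train_svm
from .netfeat import Network

#: Default (post-selection) feature schema, in documented order.
DEFAULT_FEATURES = (
    "ppi_degree",
    "ft_count",
    "pssm_wt",
    "pssm_mut",
    "pssm_delta",
    "pfam_emission_delta",
    "js_divergence",
    "first_mut_identity",
    "rsa_pred",
)


@dataclass
class FeaturePlan:
    """Feature-family toggles for `featurize`.

    ``conservation`` covers the alignment/PSSM/emission columns,
    ``network`` the PPI degree, ``tracks`` the annotation-count and
    predicted-RSA columns, and ``aa_props`` an optional extension with
    substitution-level physicochemical columns (off in the default
    nine-column plan).
    """

    conservation: bool = True
    network: bool = True
    tracks: bool = True
    aa_props: bool = False

    def __post_init__(self) -> None:
        if not (self.conservation or self.network or self.tracks or self.aa_props):
            raise ConfigError("at least one feature family must be enabled")

    def feature_names(self) -> list[str]:
        names: list[str] = []
        if self.network:
            names.append("ppi_degree")
        if self.tracks:
            names.append("ft_count")
        if self.conservation:
            names += [
                "pssm_wt",
                "pssm_mut",
                "pssm_delta",
                "pfam_emission_delta",
                "js_divergence",
                "first_mut_identity",
            ]
        if self.tracks:
            names.append("rsa_pred")
        if self.aa_props:
            names += [
                "blosum",
                "charge_delta",
                "to_gly",
                "from_gly",
                "to_pro",
                "from_pro",
            ] + [f"atchley_delta_{i}" for i in range(1, 6)]
        # keep documented order for the default plan
        if self.conservation and self.network and self.tracks and not self.aa_props:
            return list(DEFAULT_FEATURES)
        return names


@dataclass
class FeatureInputs:
    """Per-protein evidence consumed by `featurize`. Absent evidence for
    a protein yields missing feature values, never an error."""

    proteins: Mapping[str, ProteinRecord] = field(default_factory=dict)
    msas: Mapping[str, MSA] = field(default_factory=dict)
    pssms: Mapping[str, PSSM] = field(default_factory=dict)
    emissions: Mapping[str, Mapping[int, Mapping[str, float]]] = field(default_factory=dict)
    ppi: Network | None = None


def featurize(
    savs: Sequence[SAV],
    inputs: FeatureInputs,
    plan: FeaturePlan | None = None,
) -> FeatureMatrix:
    """One feature row per SAV under the given plan.

    Evidence a protein lacks (no alignment, absent from the interactome,
    uncovered track position) becomes a masked-missing entry, imputed
    later at model time.
    """
    plan = plan or FeaturePlan()
    names = plan.feature_names()
    columns: dict[str, list[float]] = {n: [] for n in names}

    ppi_degree = None
    if plan.network and inputs.ppi is not None and inputs.ppi.graph.number_of_nodes():
        ppi_degree = netfeat.centrality(inputs.ppi, "degree")

    for sav in savs:
        pid = sav.protein_id
        row: dict[str, float] = {n: math.nan for n in names}
        if plan.network:
            row["ppi_degree"] = (
                ppi_degree.get(pid, math.nan) if ppi_degree is not None else math.nan
            )
        if plan.tracks:
            rec = inputs.proteins.get(pid)
            if rec is not None:
                row["ft_count"] = float(aa_props.annotation_count(rec, sav.position))
                row["rsa_pred"] = rec.track_value("rsa_pred", sav.position)
        if plan.conservation:
            pssm = inputs.pssms.get(pid)
            msa = inputs.msas.get(pid)
            if pssm is None and msa is not None:
                pssm = conservation.compute_pssm_from_msa(msa)
            if pssm is not None and sav.position <= pssm.positions:
                feats = conservation.pssm_features(pssm, sav)
                row["pssm_wt"] = feats["wt_score"]
                row["pssm_mut"] = feats["mut_score"]
                row["pssm_delta"] = feats["delta"]
            row["pfam_emission_delta"] = conservation.pfam_emission_delta(
                inputs.emissions.get(pid), sav
            )
            if msa is not None and sav.position <= len(msa.query_columns()):
                col = msa.column_for_position(sav.position)
                jsd = conservation.js_divergence(msa, col)
                row["js_divergence"] = math.nan if jsd is None else jsd
                div = conservation.divergence_features(msa, sav)
                row["first_mut_identity"] = div["first_mut_identity"]
        if plan.aa_props:
            sub = aa_props.substitution_features(sav)
            row["blosum"] = float(sub["blosum"])
            row["charge_delta"] = float(sub["charge_delta"])
            for flag in ("to_gly", "from_gly", "to_pro", "from_pro"):
                row[flag] = float(sub[flag])
            for i, d in enumerate(sub["atchley_delta"], start=1):
                row[f"atchley_delta_{i}"] = float(d)
        for n in names:
            columns[n].append(row[n])

    return FeatureMatrix.from_columns(list(savs), columns)


# ---------------------------------------------------------------------------
# Cross-validation


def _protein_folds(savs: Sequence[SAV], folds: int) -> list[np.ndarray]:
    """Greedy by-protein fold assignment, largest protein first."""
    by_protein: dict[str, list[int]] = {}
    for i, s in enumerate(savs):
        by_protein.setdefault(s.protein_id, []).append(i)
    if len(by_protein) < folds:
        raise DegenerateInputError(
            f"cannot form {folds} by-protein folds from {len(by_protein)} proteins"
        )
    n = len(savs)
    if max(len(v) for v in by_protein.values()) > n / folds:
        logger.warning("a protein exceeds n/folds SAVs; folds will be imbalanced")
    sizes = [0] * folds
    assignment: list[list[int]] = [[] for _ in range(folds)]
    for pid in sorted(by_protein, key=lambda p: (-len(by_protein[p]), p)):
        k = int(np.argmin(sizes))
        assignment[k].extend(by_protein[pid])
        sizes[k] += len(by_protein[pid])
    return [np.array(sorted(a), dtype=int) for a in assignment]


def run_cv(
    m: FeatureMatrix,
    labels: np.ndarray | None = None,
    folds: int = 10,
    grouping: str = "by_sav",
    cfg: RunConfig | None = None,
    seed: int = 0,
) -> dict:
    """K-fold cross-validation of the scorer on a feature matrix.

    ``by_sav`` uses stratified folds over variants; ``by_protein`` keeps
    all variants of one protein in the same fold (assigned greedily by
    descending variant count to balance fold sizes). Returns per-fold
    evaluation reports and a pooled report over out-of-fold scores.
    """
    from sklearn.model_selection import StratifiedKFold

    cfg = cfg or RunConfig(seed=seed)
    if labels is None:
        labels = m.labels
    labels = np.asarray(labels, int)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if grouping == "by_sav":
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=child_seed(seed, 20)
        )
        splits = [test for _, test in skf.split(m.values, labels)]
    elif grouping == "by_protein":
        splits = _protein_folds(m.savs, folds)
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")

    fold_reports = []
    pooled_scores = np.full(m.n_savs, np.nan)
    for k, test_idx in enumerate(splits):
        train_idx = np.setdiff1d(np.arange(m.n_savs), test_idx)
        if len(np.unique(labels[train_idx])) < 2 or len(np.unique(labels[test_idx])) < 2:
            logger.warning("fold %d skipped: single-class split", k)
            continue
        trained = train_svm(
            m.select_rows(train_idx), labels[train_idx], cfg.svm, child_seed(seed, 21, k)
        )
        pred = predict_score(trained, m.select_rows(test_idx), cutoff=cfg.score_cutoff)
        pooled_scores[test_idx] = pred["score"].to_numpy()
        fold_reports.append(
            EvalReport.from_scores(
                pred["score"].to_numpy(), labels[test_idx], cfg.score_cutoff
            )
        )
    if not fold_reports:
        raise DegenerateInputError("no usable folds")
    have = np.isfinite(pooled_scores)
    pooled = EvalReport.from_scores(pooled_scores[have], labels[have], cfg.score_cutoff)
    return {"folds": fold_reports, "pooled": pooled}


# ---------------------------------------------------------------------------
# Coverage arithmetic


def coverage_summary(counts: Mapping[str, int]) -> dict[str, float]:
    """Structural-coverage fractions from variant counts by evidence tier.

    ``counts`` maps ``pdb`` (experimental structure), ``model`` (homology
    model only) and ``none`` to variant counts; a ``total`` key may
    replace ``none``. Percentages are reported at one decimal place, as
    printed in coverage tables, together with the fold increase that
    models contribute over experimental structures alone.
    """
    pdb = int(counts["pdb"])
    model = int(counts["model"])
    total = int(counts["total"]) if "total" in counts else pdb + model + int(counts["none"])
    if total <= 0 or pdb < 0 or model < 0 or pdb + model > total:
        raise ValidationError("inconsistent coverage counts")
    if pdb == 0:
        raise DegenerateInputError("no experimentally covered variants; fold undefined")
    pdb_pct = 100.0 * pdb / total
    both_pct = 100.0 * (pdb + model) / total
    fold = (pdb + model) / pdb
    return {
        "pdb_pct": round(pdb_pct, 1),
        "pdb_model_pct": round(both_pct, 1),
        "fold_increase": fold,
        "fold_increase_rounded": round(fold),
    }
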