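"""Seeded synthetic-data generators with known ground truth.

Real training data for variant phenotype prediction (curated variant
databases, PSI-BLAST alignments against large sequence databases,
interactome downloads) cannot be bundled; these generators emulate its
statistical structure instead, with ground truth planted by
construction:

- labelled feature matrices whose informative columns are Gaussian with
  a known standardised class separation, so the Bayes-optimal AUC has a
  closed form;
- alignments with designated conserved columns and rank-based E-values;
- scale-free or Erdos-Renyi graphs whose hub nodes carry an elevated
  disease propensity.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import norm

from ._tables import AA_ALPHABET
from .conservation import MSA, MsaRow
from .core import SAV, FeatureMatrix, Label, child_seed
from .errors import ValidationError
from .netfeat import Network, NetworkKind


@dataclass
class MsaSpec:
    depth: int = 50              # rows, query included
    length: int = 40             # query residues
    #: 1-based conserved column indices; None picks every 8th column
    conserved_columns: frozenset[int] | None = None
    gap_rate: float = 0.05
    conservation_prob: float = 0.95

    def __post_init__(self) -> None:
        if self.depth < 1 or self.length < 1:
            raise ValidationError("depth and length must be positive")
        if self.conserved_columns is None:
            self.conserved_columns = frozenset(range(1, self.length + 1, 8))
        else:
            self.conserved_columns = frozenset(int(c) for c in self.conserved_columns)
        if not 0 <= self.gap_rate < 1:
            raise ValidationError("gap_rate must be in [0, 1)")
        if any(not 1 <= c <= self.length for c in self.conserved_columns):
            raise ValidationError("conserved columns outside 1..length")


@dataclass
class GraphSpec:
    model: str = "preferential_attachment"  # or "erdos_renyi"
    n_nodes: int = 300
    density: float = 2            # BA attachment count m, or ER edge prob
    hub_disease_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValidationError("n_nodes must be >= 3")
        if self.model not in ("preferential_attachment", "erdos_renyi"):
            raise ValidationError(f"unknown graph model {self.model!r}")


@dataclass
class SynthSpec:
    """Conditions of the standard synthetic study.

    Defaults mirror the published design at desk scale: 77 candidate
    features of which 9 are informative, 1000 variants per class, and a
    class separation of 1.5 standard deviations per informative feature.
    """

    n_disease: int = 1000
    n_neutral: int = 1000
    n_informative: int = 9
    n_noise: int = 68
    effect_size: float = 1.5
    msa: MsaSpec = field(default_factory=MsaSpec)
    graph: GraphSpec = field(default_factory=GraphSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_disease", "n_neutral", "n_informative", "n_noise"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")

    def bayes_auc(self) -> float:
        """Closed-form AUC of the Bayes-optimal rule on this design.

        With k informative unit-variance features shifted by d, the
        optimal discriminant is Gaussian with separation d*sqrt(k), so
        AUC = Phi(d*sqrt(k)/sqrt(2)).
        """
        delta = self.effect_size * math.sqrt(self.n_informative)
        return float(norm.cdf(delta / math.sqrt(2)))


def _synthetic_savs(labels: np.ndarray, rng: np.random.Generator) -> list[SAV]:
    savs = []
    aa = list(AA_ALPHABET)
    for i, y in enumerate(labels):
        wt, mut = rng.choice(20, size=2, replace=False)
        savs.append(
            SAV(
                protein_id=f"SYN{i:05d}",
                position=int(rng.integers(1, 500)),
                wt=aa[wt],
                mut=aa[mut],
                label=Label.DISEASE if y == 1 else Label.NEUTRAL,
            )
        )
    return savs


def gen_feature_dataset(spec: SynthSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Labelled Gaussian feature matrix with planted informative columns.

    Informative columns are N(effect_size, 1) for disease rows and
    N(0, 1) for neutral rows; noise columns are N(0, 1) throughout.
    Column names are ``inf_00..`` and ``noise_00..``; rows are shuffled
    so classes interleave.
    """
    rng = np.random.default_rng(child_seed(spec.seed, 10))
    n = spec.n_disease + spec.n_neutral
    labels = np.concatenate(
        [np.ones(spec.n_disease, int), np.zeros(spec.n_neutral, int)]
    )
    perm = rng.permutation(n)
    labels = labels[perm]
    p = spec.n_informative + spec.n_noise
    values = rng.standard_normal((n, p))
    values[labels == 1, : spec.n_informative] += spec.effect_size
    names = [f"inf_{i:02d}" for i in range(spec.n_informative)] + [
        f"noise_{i:02d}" for i in range(spec.n_noise)
    ]
    savs = _synthetic_savs(labels, rng)
    matrix = FeatureMatrix(savs, names, values, np.zeros_like(values, bool))
    return matrix, labels


def gen_msa(spec: MsaSpec, query: str | None = None, seed: int = 0) -> MSA:
    """Alignment with designated conserved columns and rank E-values.

    Conserved columns repeat the query residue with probability
    ``conservation_prob``; other columns draw uniformly over the 20
    amino acids. Gaps are i.i.d. at ``gap_rate`` in non-query rows.
    Synthetic E-values are rank-based, 1e-50 * 10^rank, so row order by
    E-value is strict and deterministic.
    """
    rng = np.random.default_rng(child_seed(seed, 11))
    aa = np.array(list(AA_ALPHABET))
    if query is None:
        query = "".join(rng.choice(aa, size=spec.length))
    elif len(query) != spec.length:
        raise ValidationError("query length != spec.length")
    rows = [MsaRow("query", query, None)]
    conserved = {c - 1 for c in spec.conserved_columns}
    for r in range(1, spec.depth):
        chars = []
        for c in range(spec.length):
            if rng.random() < spec.gap_rate:
                chars.append("-")
            elif c in conserved and rng.random() < spec.conservation_prob:
                chars.append(query[c])
            else:
                chars.append(str(rng.choice(aa)))
        evalue = 1e-50 * 10.0**r
        rows.append(MsaRow(f"hom{r:03d}", "".join(chars), evalue))
    return MSA(rows)


def gen_network(
    spec: GraphSpec, seed: int = 0
) -> tuple[Network, dict[str, float]]:
    """A graph plus per-node disease propensity increasing with degree.

    Propensity is logistic in the z-scored degree with slope
    ``hub_disease_enrichment``; sampling variant labels from it makes
    hub-attached variants disease-enriched by construction.
    """
    gseed = child_seed(seed, 12)
    if spec.model == "preferential_attachment":
        g = nx.barabasi_albert_graph(spec.n_nodes, max(1, int(spec.density)), seed=gseed)
    else:
        g = nx.erdos_renyi_graph(spec.n_nodes, float(spec.density), seed=gseed)
    g = nx.relabel_nodes(g, {i: f"P{i:04d}" for i in g.nodes})
    degrees = np.array([d for _, d in g.degree()], float)
    z = (degrees - degrees.mean()) / (degrees.std() or 1.0)
    logit = spec.hub_disease_enrichment * z
    propensity = 1.0 / (1.0 + np.exp(-logit))
    nodes = list(g.nodes)
    return Network(g, NetworkKind.PPI), dict(zip(nodes, propensity.tolist()))


def sample_node_labels(
    propensity: dict[str, float], seed: int = 0
) -> dict[str, int]:
    """Bernoulli node labels drawn from per-node disease propensity."""
    rng = np.random.default_rng(child_seed(seed, 13))
    return {node: int(rng.random() < p) for node, p in propensity.items()}
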