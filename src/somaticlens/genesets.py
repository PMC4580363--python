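"""Gene-set alteration calls, hypergeometric enrichment, mutual exclusivity.

A sample is *pathway-altered* when at least one gene of the set is
altered in the co-mutation matrix. Enrichment of a set among the
cohort's mutated genes uses the exact upper-tail hypergeometric
probability over a stated gene universe (by default the capture panel).
Mutual exclusivity — the tendency of alterations within a set to occupy
different samples — is quantified by the number of samples carrying two
or more altered set genes, with a permutation null that shuffles each
gene's sample labels independently, exactly preserving per-gene
alteration frequencies.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .landscape import CohortMutationMatrix

__all__ = [
    "GeneSet",
    "PathwayCallResult",
    "EnrichmentResult",
    "ExclusivityResult",
    "read_gmt",
    "read_gene_sets_tsv",
    "call_pathway_alteration",
    "hypergeometric_enrichment",
    "exclusivity_summary",
]


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols (uppercase-normalized, nonempty)."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs >=3 fields: {line[:60]!r}")
        sets.append(GeneSet(name=parts[0], genes=frozenset(parts[2:]), source=parts[1]))
    return sets


def read_gene_sets_tsv(path: str | Path) -> list[GeneSet]:
    """Read a two-column TSV (set_name <TAB> gene, one gene per row)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"])
    return [
        GeneSet(name=name, genes=frozenset(group["gene"]))
        for name, group in df.groupby("set_name", sort=True)
    ]


@dataclass
class PathwayCallResult:
    """Per-sample alteration status of one gene set."""

    set_name: str
    altered: pd.Series  # bool per sample, full roster
    contributing_genes: dict[str, list[str]]
    missing_genes: list[str]  # set members absent from the matrix

    @property
    def n_altered(self) -> int:
        return int(self.altered.sum())

    @property
    def fraction_altered(self) -> float:
        return float(self.altered.mean())


def call_pathway_alteration(m: CohortMutationMatrix, gs: GeneSet) -> PathwayCallResult:
    """A sample is altered iff any set gene is altered in the matrix.

    Set genes absent from the matrix contribute nothing and are reported
    in ``missing_genes``; a fully disjoint set yields a zero result with
    a warning.
    """
    present = [g for g in sorted(gs.genes) if g in m.altered.columns]
    missing = [g for g in sorted(gs.genes) if g not in m.altered.columns]
    if not present:
        warnings.warn(
            f"gene set {gs.name!r} shares no genes with the matrix", stacklevel=2
        )
        altered = pd.Series(False, index=m.altered.index)
        return PathwayCallResult(gs.name, altered, {}, missing)
    sub = m.altered[present]
    altered = sub.any(axis=1)
    contributing = {
        s: [g for g in present if sub.loc[s, g]]
        for s in m.samples
        if altered[s]
    }
    return PathwayCallResult(gs.name, altered, contributing, missing)


@dataclass(frozen=True)
class EnrichmentResult:
    """Exact hypergeometric overlap test of a set vs the mutated genes."""

    set_name: str
    overlap: int
    set_size: int
    n_mutated: int
    universe_size: int
    p: float


def hypergeometric_enrichment(
    mutated_genes: set[str], gs: GeneSet, universe: set[str]
) -> EnrichmentResult:
    """Upper-tail probability of >= observed overlap under random draws.

    With universe size N, set size K and n mutated genes, p =
    P(X >= k) for X ~ Hypergeom(N, K, n). Genes outside the universe are
    an error (the offenders are listed).
    """
    universe = {g.upper() for g in universe}
    mutated = {g.upper() for g in mutated_genes}
    bad = (mutated | gs.genes) - universe
    if bad:
        raise ValueError(f"genes outside the universe: {sorted(bad)[:10]}")
    overlap = len(mutated & gs.genes)
    N, K, n = len(universe), len(gs.genes), len(mutated)
    p = float(hypergeom.sf(overlap - 1, N, K, n))
    return EnrichmentResult(
        set_name=gs.name, overlap=overlap, set_size=K,
        n_mutated=n, universe_size=N, p=min(p, 1.0),
    )


@dataclass
class ExclusivityResult:
    """Observed co-occurrence and its permutation/enumeration p-value.

    ``cooccurrence`` counts samples altered in >= 2 set genes; the null
    permutes each gene's sample labels independently (per-gene
    frequencies preserved exactly) and p is the fraction of null draws
    with co-occurrence <= observed (small p = more exclusive than
    chance).
    """

    set_name: str
    cooccurrence: int
    pair_counts: pd.DataFrame  # genes x genes co-alteration counts
    p: float
    n_null: int
    method: str


def _cooccurrence(mat: np.ndarray) -> int:
    return int((mat.sum(axis=1) >= 2).sum())


def exclusivity_summary(
    m: CohortMutationMatrix,
    gs: GeneSet,
    n_permutations: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> ExclusivityResult:
    """Test whether alterations in the set co-occur less than chance.

    ``method="exhaustive"`` enumerates all joint column permutations
    (only feasible for tiny matrices) and is the exact reference for the
    default Monte Carlo permutation test.
    """
    present = [g for g in sorted(gs.genes) if g in m.altered.columns]
    if len(present) < 2:
        raise ValueError("need >= 2 set genes present in the matrix")
    mat = m.altered[present].values.astype(bool)
    n_samples = mat.shape[0]
    observed = _cooccurrence(mat)
    pair_counts = pd.DataFrame(
        (mat.astype(int).T @ mat.astype(int)), index=present, columns=present
    )
    np.fill_diagonal(pair_counts.values, 0)

    if method == "exhaustive":
        perms = list(itertools.permutations(range(n_samples)))
        hits = total = 0
        for combo in itertools.product(perms, repeat=mat.shape[1]):
            null = np.column_stack(
                [mat[list(order), j] for j, order in enumerate(combo)]
            )
            hits += _cooccurrence(null) <= observed
            total += 1
        p = hits / total
        n_null = total
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        null = np.empty_like(mat)
        for _ in range(n_permutations):
            for j in range(mat.shape[1]):
                null[:, j] = mat[rng.permutation(n_samples), j]
            hits += _cooccurrence(null) <= observed
        p = hits / n_permutations
        n_null = n_permutations
    else:
        raise ValueError(f"unknown method {method!r}")
    return ExclusivityResult(
        set_name=gs.name, cooccurrence=observed, pair_counts=pair_counts,
        p=p, n_null=n_null, method=method,
    )
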