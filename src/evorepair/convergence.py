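"""Convergence-based detection of putatively adaptive genes and GO terms.

Independent populations evolving in parallel hit the same gene more often
than chance when mutations in that gene are under selection. The null model
is a uniform per-bp mutation rate λ, estimated as the total number of
mutations (SNPs + indels, non-synonymous/regulatory/in-CDS-indel categories)
divided by the total selection-target size in bp (CDS + 1000 bp regulatory
per ORF). The probability of observing n mutations in a target of length N
is then Poisson(λN), the reported p-value is the upper tail

    P(X ≥ n) = Σ_{k≥n} e^{-μ} μ^k / k!   with μ = λN,

computed through the regularized incomplete-gamma relation, and
Benjamini–Hochberg correction at level α over all genes with at least one
hit yields the adaptive set. ``tail="gt"`` instead evaluates
P(X > n) = 1 − Γ(n+1, μ)/n!, a variant one pmf term smaller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, DomainError, ValidationError
from .genome import GeneModel
from .variant_annotation import MUTATION_CATEGORIES


def poisson_tail(n: int, mu: float, tail: str = "ge") -> float:
    """Upper-tail Poisson probability P(X ≥ n) (or P(X > n) with ``tail="gt"``).

    Uses the identity P(X ≥ n) = P(n, μ), the regularized *lower*
    incomplete gamma function, equivalently 1 − Γ(n, μ)/(n−1)!.
    """
    if n < 0 or mu < 0:
        raise DomainError("poisson_tail requires n >= 0 and mu >= 0")
    if int(n) != n:
        raise DomainError("n must be an integer count")
    n = int(n)
    if tail == "gt":
        n = n + 1
    elif tail != "ge":
        raise ConfigError(f"tail must be 'ge' or 'gt', got {tail!r}")
    if n == 0:
        return 1.0
    return float(special.gammainc(n, mu))


@dataclass(frozen=True)
class ConvergenceModel:
    """Fitted Poisson null: per-bp rate λ over the coding target."""

    lambda_rate: float
    coding_bp: int
    total_mutations: int


def fit_null(calls: pd.DataFrame, genes: Iterable[GeneModel]) -> ConvergenceModel:
    """λ = (mutations attributed to genes) / (Σ target lengths N).

    Fit per background (e.g. WT and mutant separately): pass only that
    background's calls. Synonymous and intergenic calls do not count.
    """
    genes = list(genes)
    coding_bp = sum(g.target_length_N for g in genes)
    if coding_bp <= 0:
        raise ValidationError("fit_null requires at least one gene (coding_bp > 0)")
    in_genes = calls[
        calls["category"].isin(MUTATION_CATEGORIES) & calls["gene_id"].notna()
    ]
    total = int(len(in_genes))
    return ConvergenceModel(
        lambda_rate=total / coding_bp, coding_bp=coding_bp, total_mutations=total
    )


def gene_hits(calls: pd.DataFrame, dedup_per_population: bool = False) -> pd.Series:
    """Pooled per-gene mutation counts across populations.

    By default every mutation counts (several hits to one gene within one
    population all add to n); ``dedup_per_population=True`` counts each
    (population, gene) pair at most once.
    """
    m = calls[calls["category"].isin(MUTATION_CATEGORIES) & calls["gene_id"].notna()]
    if dedup_per_population and "population" in m.columns:
        m = m.drop_duplicates(subset=["population", "gene_id"])
    return m.groupby("gene_id").size().sort_index()


def _bh_table(units: list[str], n: np.ndarray, expected: np.ndarray,
              alpha: float, tail: str) -> pd.DataFrame:
    p = np.array([poisson_tail(int(k), mu, tail=tail) for k, mu in zip(n, expected)])
    if len(p):
        reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    else:
        reject, q = np.array([], dtype=bool), np.array([])
    out = pd.DataFrame(
        {"unit_id": units, "n_hits": n, "expected": expected,
         "p_value": p, "q_value": q, "adaptive": reject}
    )
    return out.sort_values(["p_value", "unit_id"], kind="stable").reset_index(drop=True)


def call_adaptive(
    calls: pd.DataFrame,
    genes: Iterable[GeneModel],
    model: ConvergenceModel | None = None,
    alpha: float = 0.05,
    exclude: Iterable[str] = (),
    tail: str = "ge",
    dedup_per_population: bool = False,
) -> pd.DataFrame:
    """Per-gene convergence test with BH correction.

    The tested family is every gene with n ≥ 1 pooled hits (zero-hit genes
    have p = 1 and are not tested); genes in ``exclude`` — typically those
    already significant in the control background — are removed before
    testing. Returns a frame (unit_id, n_hits, expected, p_value, q_value,
    adaptive) sorted by p, with the fitted model recorded in ``.attrs``.
    """
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must lie in (0,1), got {alpha}")
    genes = list(genes)
    if model is None:
        model = fit_null(calls, genes)
    exclude = set(exclude)
    hits = gene_hits(calls, dedup_per_population=dedup_per_population)
    hits = hits[~hits.index.isin(exclude)]
    n_by_gene = {g.gene_id: g for g in genes}
    unknown = set(hits.index) - set(n_by_gene)
    if unknown:
        raise ValidationError(f"calls reference genes absent from annotation: {sorted(unknown)[:5]}")
    units = list(hits.index)
    expected = np.array([model.lambda_rate * n_by_gene[u].target_length_N for u in units])
    out = _bh_table(units, hits.to_numpy(), expected, alpha, tail)
    out.attrs.update(
        {"lambda": model.lambda_rate, "coding_bp": model.coding_bp,
         "total_mutations": model.total_mutations, "alpha": alpha, "tail": tail,
         "excluded": sorted(exclude), "dedup_per_population": dedup_per_population,
         "bh_family": "genes with n >= 1"}
    )
    return out


def go_term_test(
    calls: pd.DataFrame,
    gene_to_terms: Mapping[str, Iterable[str]] | pd.DataFrame,
    genes: Iterable[GeneModel],
    model: ConvergenceModel | None = None,
    alpha: float = 0.05,
    tail: str = "ge",
    dedup_per_population: bool = False,
) -> pd.DataFrame:
    """Convergence test with GO terms, instead of genes, as the unit.

    A term's hit count is the sum over member genes of their pooled hits
    and its expectation is λ × Σ member target lengths. ``gene_to_terms``
    is a mapping or a two-column (gene_id, term) frame. Terms with no
    annotated member gene are skipped with a warning.
    """
    genes = list(genes)
    if model is None:
        model = fit_null(calls, genes)
    if isinstance(gene_to_terms, pd.DataFrame):
        pairs = gene_to_terms.iloc[:, :2].to_numpy()
        mapping: dict[str, list[str]] = {}
        for gene_id, term in pairs:
            mapping.setdefault(str(gene_id), []).append(str(term))
        gene_to_terms = mapping
    by_gene = {g.gene_id: g for g in genes}
    members: dict[str, list[str]] = {}
    for gene_id, terms in gene_to_terms.items():
        for term in terms:
            members.setdefault(term, []).append(gene_id)
    hits = gene_hits(calls, dedup_per_population=dedup_per_population)
    units, n, expected = [], [], []
    for term, gene_ids in sorted(members.items()):
        annotated = [g for g in gene_ids if g in by_gene]
        if not annotated:
            warnings.warn(f"GO term {term!r} has no annotated member genes; skipped")
            continue
        term_n = int(hits.reindex(annotated).fillna(0).sum())
        if term_n == 0:
            continue
        units.append(term)
        n.append(term_n)
        expected.append(model.lambda_rate * sum(by_gene[g].target_length_N for g in annotated))
    out = _bh_table(units, np.array(n, dtype=int), np.array(expected), alpha, tail)
    out.attrs.update({"lambda": model.lambda_rate, "alpha": alpha, "tail": tail,
                      "unit": "go_term"})
    return out


class ConditionPartition(NamedTuple):
    membership: pd.DataFrame
    counts: pd.Series


def condition_partition(sets: Mapping[str, Iterable[str]]) -> ConditionPartition:
    """Shared/unique membership of adaptive sets across ≥2 conditions.

    Returns a boolean membership matrix (units × conditions) and counts per
    intersection region keyed by '+'-joined condition labels (the Venn
    regions with nonzero counts).
    """
    if len(sets) < 2:
        raise ValidationError("condition_partition needs at least 2 condition sets")
    conditions = list(sets)
    universe = sorted(set().union(*[set(v) for v in sets.values()]))
    membership = pd.DataFrame(
        {c: [u in set(sets[c]) for u in universe] for c in conditions}, index=universe
    )
    if universe:
        labels = membership.apply(
            lambda row: "+".join([c for c in conditions if row[c]]), axis=1
        )
        counts = labels.value_counts().sort_index()
    else:
        counts = pd.Series(dtype=int)
    return ConditionPartition(membership, counts)
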