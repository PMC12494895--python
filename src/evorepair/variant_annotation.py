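"""Classification of ancestor-vs-evolved variants and mutational-profile statistics.

A called difference between an evolved population and its ancestor is
labelled a *mutation* when it (1) causes a non-synonymous substitution in a
coding region, (2) is an indel in a coding region, or (3) falls in a
regulatory region, defined as the 500 bp upstream or downstream of a CDS.
Synonymous in-CDS substitutions are labelled and retained (they feed the
synonymous-count analysis) but are excluded from the mutation set used by
the convergence test; everything else is intergenic.

Variants are plain :class:`pandas.DataFrame` tables — at minimum columns
``population, chrom, pos (1-based), ref, alt, fraction``. A variant falling
inside two genes' targets is assigned to each (one call row per gene), a
deliberately conservative convention for gene-level counting.
"""

from __future__ import annotations

import warnings
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy import stats

from .exceptions import CoordinateError, InsufficientDataError, ValidationError
from .genome import GeneModel, Genome

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

#: categories counted as mutations by the downstream convergence analysis
MUTATION_CATEGORIES = frozenset({"nonsynonymous", "frameshift_or_indel", "regulatory"})
ALL_CATEGORIES = MUTATION_CATEGORIES | {"synonymous", "intergenic"}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def subtract_ancestor(ancestor: pd.DataFrame, evolved: pd.DataFrame) -> pd.DataFrame:
    """Evolved variants absent from the ancestor at identical (chrom,pos,ref,alt).

    The ancestor table is a clonal call set (the ``population`` column, if
    present, is ignored for matching). Duplicate keys within either table
    raise :class:`ValidationError`.
    """
    if ancestor is None or len(ancestor) == 0:
        return evolved.reset_index(drop=True)
    if ancestor.duplicated(subset=VARIANT_KEY).any():
        raise ValidationError("ancestor table contains duplicated (chrom,pos,ref,alt) keys")
    group = (["population"] if "population" in evolved.columns else []) + VARIANT_KEY
    if evolved.duplicated(subset=group).any():
        raise ValidationError("evolved table contains duplicated variant keys within a population")
    anc_keys = set(map(tuple, ancestor[VARIANT_KEY].itertuples(index=False)))
    mask = [
        tuple(row) not in anc_keys
        for row in evolved[VARIANT_KEY].itertuples(index=False)
    ]
    return evolved.loc[mask].reset_index(drop=True)


def _gene_trees(genome: Genome) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genome.genes:
        lo = max(1, g.span_start)
        hi = min(len(genome.contigs[g.chrom]), g.span_end)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g)
    return trees


def _classify_in_gene(pos: int, ref: str, alt: str, gene: GeneModel) -> str:
    if not (gene.cds_start <= pos <= gene.cds_end):
        return "regulatory"
    if len(ref) != len(alt):
        return "frameshift_or_indel"
    # substitution (possibly multi-nucleotide): mutate the coding-strand CDS
    cds = list(gene.cds_sequence)
    changed: set[int] = set()
    for k in range(len(ref)):
        p = pos + k
        if not (gene.cds_start <= p <= gene.cds_end):
            continue  # MNV tail running past the CDS boundary
        if gene.strand == "+":
            off = p - gene.cds_start
            cds[off] = alt[k]
        else:
            off = gene.cds_end - p
            cds[off] = alt[k].translate(_COMPLEMENT)
        changed.add(off // 3)
    mutant = "".join(cds)
    for codon_i in sorted(changed):
        a, b = 3 * codon_i, 3 * codon_i + 3
        if str(Seq(gene.cds_sequence[a:b]).translate()) != str(Seq(mutant[a:b]).translate()):
            return "nonsynonymous"
    return "synonymous"


def classify_variants(
    variants: pd.DataFrame,
    genome: Genome,
    min_fraction: float = 0.0,
) -> pd.DataFrame:
    """Assign each variant a gene and category.

    Output has the input columns plus ``gene_id`` (NA for intergenic) and
    ``category``; a variant overlapping several gene targets yields one row
    per gene. ``min_fraction`` drops variants below a supporting-read
    fraction threshold (default 0: the upstream caller's output is trusted).
    Positions outside the genome raise :class:`CoordinateError`.
    """
    trees = _gene_trees(genome)
    if min_fraction > 0 and "fraction" in variants.columns:
        variants = variants[variants["fraction"] >= min_fraction]
    rows = []
    for rec in variants.itertuples(index=False):
        d = rec._asdict()
        chrom, pos = d["chrom"], int(d["pos"])
        if chrom not in genome.contigs:
            raise CoordinateError(f"unknown contig {chrom!r}")
        if not 1 <= pos <= len(genome.contigs[chrom]):
            raise CoordinateError(f"{chrom}:{pos} outside contig of length "
                                  f"{len(genome.contigs[chrom])}")
        hits = trees[chrom][pos] if chrom in trees else ()
        if not hits:
            rows.append({**d, "gene_id": pd.NA, "category": "intergenic"})
            continue
        for iv in sorted(hits, key=lambda iv: iv.data.gene_id):
            gene: GeneModel = iv.data
            rows.append(
                {**d, "gene_id": gene.gene_id,
                 "category": _classify_in_gene(pos, str(d["ref"]), str(d["alt"]), gene)}
            )
    out = pd.DataFrame(rows, columns=list(variants.columns) + ["gene_id", "category"])
    return out.reset_index(drop=True)


def mutation_set(calls: pd.DataFrame) -> pd.DataFrame:
    """Calls in the categories counted as mutations downstream."""
    return calls[calls["category"].isin(MUTATION_CATEGORIES)].reset_index(drop=True)


class ProfileSummary(NamedTuple):
    per_population: pd.DataFrame
    comparisons: pd.DataFrame


def profile_statistics(
    calls: pd.DataFrame,
    genotype_col: str = "genotype",
    condition_col: str = "condition",
    populations: pd.DataFrame | None = None,
) -> ProfileSummary:
    """Per-population mutation counts plus the standard two-sample comparisons.

    Counts per population: CDS mutations (non-synonymous + in-CDS indels),
    synonymous mutations, regulatory mutations and the median read fraction.
    Comparisons: Mann–Whitney U between genotypes on CDS and synonymous
    counts, Kolmogorov–Smirnov between genotypes' read-fraction
    distributions, and Kruskal–Wallis across conditions within each
    genotype. Populations absent from ``calls`` (zero mutations) can be
    supplied via ``populations`` (columns population/genotype/condition) to
    enter the count tests as zeros. Groups with fewer than two populations
    are skipped with a warning.
    """
    for col in ("population", genotype_col, condition_col):
        if col not in calls.columns:
            raise ValidationError(f"calls table lacks required column {col!r}")
    cds = calls["category"].isin(("nonsynonymous", "frameshift_or_indel"))
    per_pop = (
        calls.groupby(["population", genotype_col, condition_col], observed=True)
        .apply(
            lambda g: pd.Series(
                {
                    "n_cds": int(cds.loc[g.index].sum()),
                    "n_synonymous": int((g["category"] == "synonymous").sum()),
                    "n_regulatory": int((g["category"] == "regulatory").sum()),
                    "median_fraction": float(g["fraction"].median())
                    if "fraction" in g.columns
                    else np.nan,
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    if populations is not None:
        missing = populations[~populations["population"].isin(per_pop["population"])]
        if len(missing):
            zeros = missing.assign(
                n_cds=0, n_synonymous=0, n_regulatory=0, median_fraction=np.nan
            )
            per_pop = pd.concat([per_pop, zeros], ignore_index=True)

    results = []
    genotypes = sorted(per_pop[genotype_col].unique())

    def _group_ok(name, values) -> bool:
        if len(values) < 2:
            warnings.warn(f"group {name!r} has <2 populations; comparison skipped")
            return False
        return True

    for i, ga in enumerate(genotypes):
        for gb in genotypes[i + 1 :]:
            xa = per_pop.loc[per_pop[genotype_col] == ga]
            xb = per_pop.loc[per_pop[genotype_col] == gb]
            if not (_group_ok(ga, xa) and _group_ok(gb, xb)):
                continue
            for metric in ("n_cds", "n_synonymous"):
                s = stats.mannwhitneyu(xa[metric], xb[metric], alternative="two-sided")
                results.append(
                    {"test": "mannwhitneyu", "metric": metric, "group_a": ga,
                     "group_b": gb, "statistic": s.statistic, "p_value": s.pvalue}
                )
            fa = calls.loc[calls[genotype_col] == ga, "fraction"].dropna()
            fb = calls.loc[calls[genotype_col] == gb, "fraction"].dropna()
            if len(fa) and len(fb):
                s = stats.ks_2samp(fa, fb)
                results.append(
                    {"test": "ks_2samp", "metric": "fraction", "group_a": ga,
                     "group_b": gb, "statistic": s.statistic, "p_value": s.pvalue}
                )
    for g in genotypes:
        sub = per_pop.loc[per_pop[genotype_col] == g]
        groups = [grp["n_cds"].to_numpy() for _, grp in sub.groupby(condition_col, observed=True)]
        usable = [x for x in groups if _group_ok(g, x)]
        if len(usable) >= 2:
            s = stats.kruskal(*usable)
            results.append(
                {"test": "kruskal", "metric": "n_cds", "group_a": g,
                 "group_b": "conditions", "statistic": s.statistic, "p_value": s.pvalue}
            )
    return ProfileSummary(per_pop, pd.DataFrame(results))


def read_variant_table(path) -> pd.DataFrame:
    """Read the package's TSV variant dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: variant table lacks columns {sorted(missing)}")
    return df


def write_variant_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_vcf(path, population: str | None = None, fraction_tag: str = "AF") -> pd.DataFrame:
    """Read a minimal VCF into the package's variant-table dialect.

    Only CHROM/POS/REF/ALT and a per-record INFO fraction tag (default
    ``AF``) are consumed; multi-allelic records are split. Parsing is
    line-based so plain-text VCFs work without an index.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValidationError(f"{path}:{lineno}: expected >=8 VCF columns")
            chrom, pos, _, ref, alts, _, _, info = parts[:8]
            frac = np.nan
            for kv in info.split(";"):
                if kv.startswith(fraction_tag + "="):
                    frac = float(kv.split("=", 1)[1].split(",")[0])
            for alt in alts.split(","):
                rows.append(
                    {"population": population, "chrom": chrom, "pos": int(pos),
                     "ref": ref, "alt": alt, "fraction": frac}
                )
    return pd.DataFrame(rows, columns=["population", "chrom", "pos", "ref", "alt", "fraction"])
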