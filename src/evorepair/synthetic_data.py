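"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the data structure of a serial-dilution evolution
experiment on budding yeast under replication stress: a toy genome with
annotated ORFs, per-population variant tables whose per-gene hit counts are
Poisson under the null (with optional planted convergent genes), flow
cytometry event counts from competition assays under a known selection
coefficient, power-law fitness trajectories, 100-bp read-depth tracks with
planted segmental amplifications, two-peak (1C/2C) DNA-content samples, and
logistic OD600 growth curves.

Every generator draws from a single :class:`numpy.random.Generator` created
from its seed argument — no global random state — so identical seeds give
byte-identical outputs.

Defaults mirror the study layout these analyses were designed around:
12 populations per condition, four glucose concentrations (0.25/0.5/2/8%),
two genotypes, ~10 generations per daily passage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, CoordinateError, DomainError, SizingError, ValidationError
from .genome import GeneModel, Genome, cds_sequence_from_contig

VARIANT_COLUMNS = ["population", "genotype", "condition", "chrom", "pos", "ref", "alt", "fraction"]
_BASES = np.array(list("ACGT"))

#: depth tracks are defined on fixed 100-bp windows throughout the package
DEPTH_WINDOW = 100


@dataclass
class SimulationConfig:
    """Study-level layout and generative rates for the variant-table generator.

    ``per_base_rate`` is the per-population, per-bp mutation rate over each
    gene's CDS+regulatory target — the generative counterpart of the λ the
    convergence test estimates. ``planted_genes`` maps gene ids to rate
    multipliers (≥1) to plant convergent targets. The read-fraction model is
    a two-component Beta mixture: a near-fixed component (weight per
    genotype, higher for the stressed mutant to mimic its clonality skew)
    and a low-frequency component.
    """

    seed: int = 0
    n_populations_per_condition: int = 12
    conditions: tuple[str, ...] = ("0.25", "0.5", "2", "8")
    genotypes: tuple[str, ...] = ("WT", "mutant")
    per_base_rate: float = 1e-5
    planted_genes: dict[str, float] = field(default_factory=dict)
    genotype_rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "mutant": 3.5}
    )
    indel_fraction: float = 0.1
    fixed_component_weight: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.3, "mutant": 0.7}
    )
    fixed_beta: tuple[float, float] = (20.0, 1.5)
    low_beta: tuple[float, float] = (1.5, 8.0)
    true_selection_coefficient: float = 0.05
    trajectory_params: tuple[float, float, float] = (0.5, 0.01, -0.3)
    depth_noise_sd: float = 0.0
    od_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.per_base_rate < 0:
            raise ConfigError("per_base_rate must be >= 0")
        for gene, mult in self.planted_genes.items():
            if mult < 1:
                raise ConfigError(f"planted multiplier for {gene} must be >= 1, got {mult}")
        for g, m in self.genotype_rate_multiplier.items():
            if m < 0:
                raise ConfigError(f"genotype multiplier for {g} must be >= 0")
        if not 0 <= self.indel_fraction <= 1:
            raise ConfigError("indel_fraction must lie in [0, 1]")


def gen_genome(
    n_genes: int = 200,
    gene_length_dist: tuple = ("lognormal", 1500, 0.35),
    seed: int = 0,
    n_contigs: int = 2,
    contig_length: int | None = None,
    min_gap: int = 1100,
) -> Genome:
    """Generate a toy genome: random contigs carrying non-overlapping genes.

    ``gene_length_dist`` is ``("constant", L)`` or ``("lognormal", mean,
    sigma)``; drawn CDS lengths are rounded to multiples of 3 (minimum 300).
    Genes are placed on both strands with at least ``min_gap`` bp between
    CDSs, so each ±500 bp regulatory window stays within its own gene's
    territory. If ``contig_length`` is given and the genes do not fit, a
    :class:`SizingError` is raised; otherwise contigs are sized to fit.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)

    kind = gene_length_dist[0]
    if kind == "constant":
        lengths = np.full(n_genes, int(gene_length_dist[1]))
    elif kind == "lognormal":
        mean, sigma = float(gene_length_dist[1]), float(gene_length_dist[2])
        mu = np.log(mean) - sigma**2 / 2.0
        lengths = rng.lognormal(mu, sigma, size=n_genes)
    else:
        raise ConfigError(f"unknown gene_length_dist kind {kind!r}")
    lengths = np.maximum(300, (np.rint(lengths / 3.0) * 3).astype(int))
    if np.any(lengths % 3):  # constant lengths must already be codon-sized
        raise ConfigError("gene lengths must be multiples of 3")

    # round-robin assignment of genes to contigs
    per_contig: list[list[int]] = [[] for _ in range(n_contigs)]
    for i in range(n_genes):
        per_contig[i % n_contigs].append(i)

    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci, idxs in enumerate(per_contig):
        chrom = f"contig_{ci + 1}"
        cursor = 601  # room for a full upstream regulatory window
        placements = []
        for gi in idxs:
            start = cursor + int(rng.integers(0, 400))
            end = start + int(lengths[gi]) - 1
            placements.append((gi, start, end))
            cursor = end + min_gap
        needed = (placements[-1][2] + 600) if placements else 1200
        total = contig_length if contig_length is not None else needed
        if total < needed:
            raise SizingError(
                f"{chrom}: {len(idxs)} genes need {needed} bp but contig_length={total}"
            )
        seq = "".join(rng.choice(_BASES, size=total))
        contigs[chrom] = seq
        for gi, start, end in placements:
            # alternate strands so both are always represented
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gi + 1:04d}",
                    chrom=chrom,
                    strand=strand,
                    cds_start=start,
                    cds_end=end,
                    cds_sequence=cds_sequence_from_contig(seq, strand, start, end),
                )
            )
    genes.sort(key=lambda g: g.gene_id)
    return Genome(contigs=contigs, genes=genes)


def _draw_fractions(rng: np.random.Generator, n: int, w_fixed: float,
                    fixed_beta: tuple[float, float], low_beta: tuple[float, float]) -> np.ndarray:
    fixed = rng.random(n) < w_fixed
    out = np.empty(n)
    out[fixed] = rng.beta(*fixed_beta, size=int(fixed.sum()))
    out[~fixed] = rng.beta(*low_beta, size=int((~fixed).sum()))
    return out


def gen_mutation_tables(genome: Genome, config: SimulationConfig) -> pd.DataFrame:
    """Per-population variant tables with Poisson per-gene hit counts.

    For each population, each gene's mutation count is Poisson with mean
    ``per_base_rate × genotype_multiplier × planted_multiplier × N`` where
    ``N`` is the gene's CDS+regulatory target length; positions are uniform
    within the target window, ref is the genome base, alt a random other
    base (or a 1-bp insertion with probability ``indel_fraction``), and read
    fractions follow the genotype's Beta mixture.

    Returns one long table (columns :data:`VARIANT_COLUMNS`) covering every
    population; an empty table (rate 0) is valid output.
    """
    rng = np.random.default_rng(config.seed)
    genes = genome.genes
    n_genes = len(genes)
    target_n = np.array([g.target_length_N for g in genes], dtype=float)
    span_start = np.array([max(1, g.span_start) for g in genes])
    span_len = np.array(
        [min(len(genome.contigs[g.chrom]), g.span_end) - max(1, g.span_start) + 1
         for g in genes]
    )
    chrom_of = np.array([g.chrom for g in genes])
    planted = np.array([config.planted_genes.get(g.gene_id, 1.0) for g in genes])

    frames = []
    for genotype in config.genotypes:
        geno_mult = config.genotype_rate_multiplier.get(genotype, 1.0)
        w_fixed = config.fixed_component_weight.get(genotype, 0.5)
        for condition in config.conditions:
            for p in range(config.n_populations_per_condition):
                pop = f"{genotype}_{condition}_p{p + 1:02d}"
                mean = config.per_base_rate * geno_mult * planted * target_n
                counts = rng.poisson(mean)
                total = int(counts.sum())
                if total == 0:
                    continue
                gidx = np.repeat(np.arange(n_genes), counts)
                offs = rng.integers(0, span_len[gidx])
                pos = span_start[gidx] + offs
                refs = np.array(
                    [genome.contigs[chrom_of[i]][p0 - 1] for i, p0 in zip(gidx, pos)]
                )
                is_indel = rng.random(total) < config.indel_fraction
                alt_snv = _BASES[
                    (np.searchsorted(_BASES, refs) + rng.integers(1, 4, size=total)) % 4
                ]
                ins_base = rng.choice(_BASES, size=total)
                alts = np.where(is_indel, np.char.add(refs, ins_base), alt_snv)
                fracs = _draw_fractions(rng, total, w_fixed, config.fixed_beta, config.low_beta)
                frames.append(
                    pd.DataFrame(
                        {
                            "population": pop,
                            "genotype": genotype,
                            "condition": condition,
                            "chrom": chrom_of[gidx],
                            "pos": pos,
                            "ref": refs,
                            "alt": alts,
                            "fraction": np.round(fracs, 4),
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    # identical draws at one site in one population collapse to a single call
    table = table.drop_duplicates(subset=["population", "chrom", "pos", "ref", "alt"])
    return table.sort_values(["population", "chrom", "pos"], kind="stable").reset_index(drop=True)


def gen_competition_counts(
    s_true: float,
    init_ratio: float = 1.0,
    gens_per_day: float = 10.0,
    days: int = 2,
    n_events: int = 10_000,
    noise: str | None = None,
    seed: int | None = None,
    initial_cells: float = 1e5,
) -> pd.DataFrame:
    """Flow-cytometry event counts from a competition assay with known ``s_true``.

    ln(ratio) of test (non-fluorescent) to reference (fluorescent) events
    increases by ``s_true`` per generation; total-cell counts encode
    ``gens_per_day`` doublings per passage, the day-0 sample anchoring
    generation 0. ``noise=None`` yields continuous (real-valued) event
    counts so the downstream regression recovers ``s_true`` exactly;
    ``noise="multinomial"`` draws integer counts of ``n_events`` per sample.
    """
    if n_events <= 0:
        raise ConfigError("n_events must be > 0")
    if noise not in (None, "multinomial"):
        raise ConfigError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for day in range(days + 1):
        g_cum = gens_per_day * day
        ratio = init_ratio * np.exp(s_true * g_cum)
        p_test = ratio / (1.0 + ratio)
        if noise == "multinomial":
            nonfluor, fluor = rng.multinomial(n_events, [p_test, 1.0 - p_test])
        else:
            nonfluor = n_events * p_test
            fluor = n_events * (1.0 - p_test)
        t0 = initial_cells
        t24 = initial_cells * (2.0**gens_per_day if day > 0 else 1.0)
        rows.append(
            {
                "day": day,
                "fluorescent_events": fluor,
                "nonfluorescent_events": nonfluor,
                "total_events_t0": t0,
                "total_events_t24": t24,
            }
        )
    return pd.DataFrame(rows)


def gen_trajectory(
    a: float,
    b: float,
    w0: float,
    timepoints,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean-fitness trajectory w̄(t) = (b·t)^a + w0 with optional Gaussian noise."""
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise DomainError("timepoints must be >= 0")
    if b < 0:
        raise DomainError("b must be >= 0")
    w = (b * t) ** a + w0
    if noise_sd > 0:
        w = w + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return pd.DataFrame({"generation": t, "fitness": w})


def gen_depth_tracks(
    genome: Genome,
    amplified_locus: tuple[str, int, int] | None = None,
    copy_number: float = 2.0,
    mean_depth: float = 50.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    window: int = DEPTH_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ancestor and evolved 100-bp depth tracks with a planted amplification.

    ``amplified_locus`` is ``(chrom, start, end)`` in 0-based half-open
    coordinates; inside it the evolved track's expected depth is
    ``copy_number × mean_depth``. The ancestor carries no event. Returns
    ``(ancestor, evolved)`` bedGraph-like frames (chrom, start, end, depth).
    """
    if window != DEPTH_WINDOW:
        raise ConfigError(f"depth windows are fixed at {DEPTH_WINDOW} bp")
    if copy_number < 1:
        raise ConfigError("copy_number must be >= 1")
    rng = np.random.default_rng(seed)
    anc_frames, evo_frames = [], []
    for chrom, seq in genome.contigs.items():
        n_win = len(seq) // window
        starts = np.arange(n_win) * window
        ends = starts + window
        anc = np.full(n_win, mean_depth)
        evo = np.full(n_win, mean_depth)
        if amplified_locus is not None and amplified_locus[0] == chrom:
            _, a0, a1 = amplified_locus
            if not (0 <= a0 < a1 <= len(seq)):
                raise CoordinateError(f"locus {amplified_locus} outside contig {chrom}")
            inside = (starts >= a0) & (ends <= a1)
            evo[inside] = mean_depth * copy_number
        if noise_sd > 0:
            anc = np.maximum(0.0, anc + rng.normal(0.0, noise_sd * mean_depth, n_win))
            evo = np.maximum(0.0, evo + rng.normal(0.0, noise_sd * mean_depth, n_win))
        anc_frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "depth": anc}))
        evo_frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "depth": evo}))
    if amplified_locus is not None and amplified_locus[0] not in genome.contigs:
        raise CoordinateError(f"unknown contig in locus {amplified_locus}")
    return (
        pd.concat(anc_frames, ignore_index=True),
        pd.concat(evo_frames, ignore_index=True),
    )


def gen_facs_sample(
    fractions: tuple[float, float, float],
    c1_position: float = 200.0,
    cv: float = 0.05,
    n_events: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """DNA-content intensities: Gaussian 1C and 2C peaks with a uniform S bridge.

    ``fractions`` are the (G1, S, G2/M) event fractions and must sum to 1.
    The 2C peak sits at exactly twice the 1C position; peak widths scale
    with position at coefficient of variation ``cv``.
    """
    frac = np.asarray(fractions, dtype=float)
    if frac.shape != (3,) or np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-6:
        raise ValidationError("fractions must be three nonnegative values summing to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n_events, p=frac)
    out = np.empty(n_events)
    g1 = labels == 0
    s = labels == 1
    g2 = labels == 2
    out[g1] = rng.normal(c1_position, cv * c1_position, int(g1.sum()))
    out[s] = rng.uniform(c1_position, 2.0 * c1_position, int(s.sum()))
    out[g2] = rng.normal(2.0 * c1_position, cv * 2.0 * c1_position, int(g2.sum()))
    return np.maximum(out, 1e-9)


def gen_od_curve(
    rate: float = 0.005,
    lag: float = 0.0,
    capacity: float = 1.2,
    init_od: float = 0.01,
    interval: float = 10.0,
    duration: float = 2880.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Logistic OD600 time series sampled every ``interval`` minutes.

    Noise-free values follow the logistic solution with per-minute growth
    rate ``rate``, saturating at ``capacity``; readings before ``lag`` stay
    at ``init_od``.
    """
    if rate <= 0:
        raise DomainError("rate must be > 0")
    t = np.arange(0.0, duration + interval / 2, interval)
    shifted = np.maximum(0.0, t - lag)
    od = capacity / (1.0 + (capacity - init_od) / init_od * np.exp(-rate * shifted))
    if noise_sd > 0:
        od = np.maximum(
            1e-6, od + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
        )
    return pd.DataFrame({"time": t, "od": od})
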