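"""Synthetic genotype, read and genotype-likelihood simulation for relative
pairs.

A pair is built site by site from four founder haplotypes: the allele
frequency is drawn from a configurable spectrum (the population's variable
sites), four founder alleles are drawn Bernoulli(p), an IBD state is
sampled from the relationship's (k0, k1, k2), and the two genotypes are
assembled from the founder alleles according to that state
(state 0: haplotypes 1+2 vs 3+4; state 1: one shared haplotype; state 2:
both shared).  IBD states are independent across sites, so linkage and the
biological variance of IBD sharing are deliberately not modelled.

Optional layers reproduce the data-quality regimes of interest: SNP
ascertainment by minor-allele count in a 40-chromosome reference panel
(MAF > 5% style filtering), Poisson-depth reads with a fixed base error rate
converted to GATK-model genotype likelihoods, cross-population unrelated
pairs via a Balding-Nichols frequency model, and random 200-bp-window site
subsetting that mimics reduced-representation (RADseq-like) data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .core import (CategoryCounts, KCoefficients, RELATIONSHIPS,
                   count_pair_matrix, pair_stats, PairStats)
from .expectations import SpectrumModel
from .gl import GLData, PAIR_INDEX, GENOTYPES10

#: Rejection-sampling rounds before declaring an ascertainment rule
#: incompatible with the spectrum.
MAX_REJECTION_ROUNDS = 200


def _resolve_k(relationship: str | KCoefficients) -> KCoefficients:
    if isinstance(relationship, KCoefficients):
        return relationship
    try:
        return RELATIONSHIPS[relationship]
    except KeyError:
        raise ValueError(
            f"unknown relationship {relationship!r}; "
            f"choose from {sorted(RELATIONSHIPS)} or pass KCoefficients")


@dataclass(frozen=True)
class PairSimConfig:
    """Configuration for simulating one relative pair.

    ``min_minor_ac`` switches on ascertainment: sites are kept only when the
    minor allele count in a ``panel_size``-chromosome reference panel (the
    four founders plus independent draws) exceeds it; 2 out of 40 reproduces
    a MAF > 5% filter.  ``n_chromosome_labels`` contiguous site blocks are
    labelled as chromosomes purely so downstream jackknifing has blocks;
    positions are placed on each chromosome at an average density of
    ``n_sites / genome_span_bp``.
    """

    relationship: str | KCoefficients
    n_sites: int
    spectrum: SpectrumModel
    seed: int
    n_chromosome_labels: int = 22
    min_minor_ac: int | None = None
    panel_size: int = 40
    record_panel: bool = False
    genome_span_bp: int = 50_000_000

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.n_chromosome_labels < 1:
            raise ValueError("need at least one chromosome label")
        if self.min_minor_ac is not None and self.panel_size < 4:
            raise ValueError("reference panel must include the four founders")
        if self.genome_span_bp < 2 * self.n_sites:
            raise ValueError("genome span too small for the number of sites")

    @property
    def k(self) -> KCoefficients:
        return _resolve_k(self.relationship)


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing-read layer: per-site depth ~ Poisson(``mean_depth``), each
    read drawn from a uniformly chosen allele of the true genotype and
    flipped to a uniform other base with probability ``error_rate``.
    Defaults mirror low-depth resequencing (~4x, Q20 bases)."""

    mean_depth: float = 4.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate must lie in (0,1)")


@dataclass
class SimulatedPair:
    """One simulated pair: genotypes, site metadata and the simulation truth.

    Genotypes count copies of the derived (``alt``) allele.  ``ibd_states``
    and ``realized_k`` record the per-site truth; ``panel_minor_count`` holds
    the reference-panel minor allele count when a panel was drawn.
    """

    g1: np.ndarray
    g2: np.ndarray
    contigs: np.ndarray
    positions: np.ndarray
    contig_lengths: Mapping[str, int]
    alleles: np.ndarray          # (n, 2) base indices 0..3: ref, alt
    freqs: np.ndarray            # per-site allele frequency drawn
    ibd_states: np.ndarray | None
    realized_k: tuple[float, float, float] | None
    config: object
    panel_minor_count: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.g1.size

    def subset(self, mask: np.ndarray) -> "SimulatedPair":
        return replace(
            self,
            g1=self.g1[mask], g2=self.g2[mask],
            contigs=self.contigs[mask], positions=self.positions[mask],
            alleles=self.alleles[mask], freqs=self.freqs[mask],
            ibd_states=None if self.ibd_states is None else self.ibd_states[mask],
            panel_minor_count=(None if self.panel_minor_count is None
                               else self.panel_minor_count[mask]),
        )

    def counts(self) -> CategoryCounts:
        return count_pair_matrix(self.g1, self.g2)

    def stats(self) -> PairStats:
        return pair_stats(self.counts())

    def block_counts(self) -> list[CategoryCounts]:
        """Per-chromosome category counts for jackknifing."""
        return [count_pair_matrix(self.g1[self.contigs == lab],
                                  self.g2[self.contigs == lab])
                for lab in dict.fromkeys(self.contigs)]


# ---------------------------------------------------------------------------
# Site and genotype simulation
# ---------------------------------------------------------------------------

def _draw_sites(rng: np.random.Generator, spectrum: SpectrumModel, n: int,
                min_minor_ac: int | None, panel_size: int,
                record_panel: bool) -> tuple[np.ndarray, np.ndarray,
                                             np.ndarray | None]:
    """Draw per-site frequencies and founder haplotypes.

    Sites model the population's variable sites, so founder alleles are
    plain Bernoulli(p) draws and a site may be monomorphic within the pair
    (it then lands in cell A or I, as in real genotype data).  With
    ascertainment, sites are drawn by rejection until the reference panel
    (the founders plus ``panel_size - 4`` extra chromosomes) has minor
    allele count above ``min_minor_ac``.
    """
    need_panel = (min_minor_ac is not None) or record_panel
    p_out = np.empty(n)
    founders_out = np.empty((n, 4), dtype=np.int8)
    minor_out = np.empty(n, dtype=np.int16) if need_panel else None

    remaining = np.arange(n)
    for _ in range(MAX_REJECTION_ROUNDS):
        if remaining.size == 0:
            break
        m = remaining.size
        p = spectrum.sample(rng, m)
        founders = (rng.random((m, 4)) < p[:, None]).astype(np.int8)
        if need_panel:
            extra = rng.binomial(panel_size - 4, p)
            derived = founders.sum(axis=1) + extra
            minor = np.minimum(derived, panel_size - derived)
            ok = (np.ones(m, dtype=bool) if min_minor_ac is None
                  else minor > min_minor_ac)
        else:
            minor = None
            ok = np.ones(m, dtype=bool)
        accept = remaining[ok]
        p_out[accept] = p[ok]
        founders_out[accept] = founders[ok]
        if need_panel:
            minor_out[accept] = minor[ok]
        remaining = remaining[~ok]
    if remaining.size:
        raise RuntimeError(
            "rejection sampling failed: the ascertainment rule is "
            "incompatible with the allele-frequency spectrum "
            f"({remaining.size} of {n} sites undrawable after "
            f"{MAX_REJECTION_ROUNDS} rounds)")
    return p_out, founders_out, minor_out


def _site_layout(rng: np.random.Generator, n: int, n_contigs: int,
                 span_bp: int) -> tuple[np.ndarray, np.ndarray, dict]:
    """Assign contiguous chromosome labels and strictly increasing positions."""
    contig_len = span_bp // n_contigs
    labels = [f"chr{i + 1}" for i in range(n_contigs)]
    blocks = np.array_split(np.arange(n), n_contigs)
    contigs = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=np.int64)
    for lab, idx in zip(labels, blocks):
        contigs[idx] = lab
        positions[idx] = np.sort(
            rng.choice(contig_len, size=idx.size, replace=False)) + 1
    return contigs.astype(str), positions, {lab: contig_len for lab in labels}


def _random_alleles(rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-site (ref, alt) base indices, distinct, uniform over {A,C,G,T}."""
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return np.column_stack([ref, alt]).astype(np.int8)


def simulate_pair_genotypes(config: PairSimConfig) -> SimulatedPair:
    """Simulate genotypes for one pair under ``config``.

    Per site: draw the allele frequency, four founder haplotypes (with
    polymorphism/ascertainment conditioning), an IBD state from
    (k0, k1, k2), and assemble the genotypes: individual 1 always carries
    haplotypes 1+2; individual 2 carries 3+4 (IBD 0), 1+3 (IBD 1) or 1+2
    (IBD 2).
    """
    rng = np.random.default_rng(config.seed)
    k = config.k
    n = config.n_sites

    p, founders, minor = _draw_sites(
        rng, config.spectrum, n, config.min_minor_ac, config.panel_size,
        config.record_panel)

    u = rng.random(n)
    ibd = np.where(u < k.k0, 0, np.where(u < k.k0 + k.k1, 1, 2)).astype(np.int8)

    h1, h2, h3, h4 = (founders[:, j] for j in range(4))
    g1 = (h1 + h2).astype(np.int8)
    g2 = np.where(ibd == 0, h3 + h4,
                  np.where(ibd == 1, h1 + h3, h1 + h2)).astype(np.int8)

    contigs, positions, lengths = _site_layout(
        rng, n, config.n_chromosome_labels, config.genome_span_bp)
    realized = tuple(np.bincount(ibd, minlength=3) / n)

    return SimulatedPair(
        g1=g1, g2=g2, contigs=contigs, positions=positions,
        contig_lengths=lengths, alleles=_random_alleles(rng, n), freqs=p,
        ibd_states=ibd, realized_k=realized, config=config,
        panel_minor_count=minor)


def simulate_cross_population_pair(fst: float, base_spectrum: SpectrumModel,
                                   n_sites: int, seed: int,
                                   n_chromosome_labels: int = 22,
                                   genome_span_bp: int = 50_000_000
                                   ) -> SimulatedPair:
    """Two unrelated individuals drawn from two populations that diverged
    from a common ancestral frequency under a Balding-Nichols model.

    Per site the ancestral frequency ``p`` comes from ``base_spectrum`` and
    each population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``fst`` (F = 0 collapses to a same-population unrelated pair); each
    individual is a Hardy-Weinberg draw from its own population.
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p = base_spectrum.sample(rng, n_sites)
    if fst == 0:
        p1 = p2 = p
    else:
        a = p * (1 - fst) / fst
        b = (1 - p) * (1 - fst) / fst
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    g1 = rng.binomial(2, p1).astype(np.int8)
    g2 = rng.binomial(2, p2).astype(np.int8)
    contigs, positions, lengths = _site_layout(
        rng, n_sites, n_chromosome_labels, genome_span_bp)
    return SimulatedPair(
        g1=g1, g2=g2, contigs=contigs, positions=positions,
        contig_lengths=lengths, alleles=_random_alleles(rng, n_sites),
        freqs=p, ibd_states=None, realized_k=None,
        config={"fst": fst, "n_sites": n_sites, "seed": seed})


# ---------------------------------------------------------------------------
# Reads and genotype likelihoods
# ---------------------------------------------------------------------------

@dataclass
class ReadSimResult:
    """Simulated reads for one individual: per-site depth, per-base read
    counts and GATK-model genotype likelihoods in both the 10-genotype and
    (given the site's ref/alt) the 3-genotype diallelic form, each scaled to
    max 1 per site."""

    depth: np.ndarray
    base_counts: np.ndarray   # (n, 4)
    gl10: np.ndarray          # (n, 10)
    gl3: np.ndarray           # (n, 3)


def _gl_log_emission_matrix(error_rate: float) -> np.ndarray:
    """(4, 10) matrix of log P(read base | genotype) under the GATK model:
    a read picks one of the genotype's two alleles with probability 1/2 and
    matches it with probability 1 - e (else one of the other bases, e/3)."""
    e = error_rate
    base_given_allele = np.full((4, 4), e / 3.0)
    np.fill_diagonal(base_given_allele, 1.0 - e)
    M = np.empty((4, 10))
    for kk, (x, y) in enumerate(GENOTYPES10):
        M[:, kk] = 0.5 * base_given_allele[:, x] + 0.5 * base_given_allele[:, y]
    return np.log(M)


def simulate_reads_and_gls(genotypes: np.ndarray, site_alleles: np.ndarray,
                           config: ReadSimConfig,
                           rng: np.random.Generator | None = None
                           ) -> ReadSimResult:
    """Simulate reads and genotype likelihoods for one individual.

    ``genotypes`` are alt-allele dosages (0/1/2) and ``site_alleles`` the
    (n, 2) ref/alt base indices.  Depth is Poisson; each read's base comes
    from a uniformly chosen allele of the true genotype and is flipped to a
    uniform different base with probability ``error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = np.asarray(genotypes, dtype=np.int64)
    n = g.size
    ref = site_alleles[:, 0].astype(np.int64)
    alt = site_alleles[:, 1].astype(np.int64)

    depth = rng.poisson(config.mean_depth, size=n)
    # reads drawn from the alt allele: all (hom alt), none (hom ref), or
    # Binomial(depth, 1/2) (het)
    n_alt = np.where(g == 2, depth,
                     np.where(g == 0, 0, rng.binomial(depth, 0.5)))
    n_ref = depth - n_alt

    counts = np.zeros((n, 4), dtype=np.int64)
    others = np.array([[b for b in range(4) if b != a] for a in range(4)])
    rows = np.arange(n)
    for src_base, n_src in ((ref, n_ref), (alt, n_alt)):
        correct = rng.binomial(n_src, 1.0 - config.error_rate)
        errors = n_src - correct
        np.add.at(counts, (rows, src_base), correct)
        err_split = rng.multinomial(errors, [1 / 3] * 3)  # (n, 3)
        np.add.at(counts, (rows[:, None], others[src_base]), err_split)

    logM = _gl_log_emission_matrix(config.error_rate)
    loggl10 = counts @ logM
    loggl10 -= loggl10.max(axis=1, keepdims=True)
    gl10 = np.exp(loggl10)

    lo = np.minimum(ref, alt)
    hi = np.maximum(ref, alt)
    idx3 = np.column_stack([PAIR_INDEX[ref, ref], PAIR_INDEX[lo, hi],
                            PAIR_INDEX[alt, alt]])
    loggl3 = loggl10[rows[:, None], idx3]
    loggl3 -= loggl3.max(axis=1, keepdims=True)
    return ReadSimResult(depth, counts, gl10, np.exp(loggl3))


def pair_gl_data(pair: SimulatedPair, config: ReadSimConfig
                 ) -> dict[str, GLData]:
    """Simulate reads for both individuals of ``pair`` and return GL streams
    in both estimator modes: ``{'sfs': diallelic3, 'ibs': tengenotype10}``."""
    rng = np.random.default_rng(config.seed)
    r1_ = simulate_reads_and_gls(pair.g1, pair.alleles, config, rng)
    r2_ = simulate_reads_and_gls(pair.g2, pair.alleles, config, rng)
    return {
        "sfs": GLData("diallelic3", r1_.gl3, r2_.gl3, pair.contigs,
                      pair.positions),
        "ibs": GLData("tengenotype10", r1_.gl10, r2_.gl10, pair.contigs,
                      pair.positions),
        "_reads": (r1_, r2_),
    }


def call_genotypes(gl3: np.ndarray, depth: np.ndarray | None = None
                   ) -> np.ndarray:
    """Naive per-site genotype calling: argmax of the 3-genotype likelihoods
    (missing where depth is zero).  The negative control for the EM
    estimators: at low depth these calls systematically miss heterozygotes.
    """
    called = np.argmax(gl3, axis=1).astype(np.int64)
    if depth is not None:
        called[depth == 0] = -1
    return called


# ---------------------------------------------------------------------------
# Ascertainment and site subsetting
# ---------------------------------------------------------------------------

def ascertain_sites(panel: np.ndarray | SimulatedPair,
                    min_minor_ac: int | None = 2) -> np.ndarray:
    """Boolean site mask from a minor-allele-count ascertainment rule.

    ``panel`` is either a (n_sites, n_chromosomes) 0/1 haplotype panel, an
    array of per-site minor allele counts, or a :class:`SimulatedPair`
    carrying recorded panel counts.  A site is kept when its minor count
    exceeds ``min_minor_ac`` (a disabled rule keeps everything).
    """
    if isinstance(panel, SimulatedPair):
        if panel.panel_minor_count is None:
            raise ValueError(
                "pair has no recorded reference panel; simulate with "
                "record_panel=True")
        minor = panel.panel_minor_count
    else:
        panel = np.asarray(panel)
        if panel.ndim == 2:
            derived = panel.sum(axis=1)
            minor = np.minimum(derived, panel.shape[1] - derived)
        else:
            minor = panel
    if min_minor_ac is None:
        return np.ones(minor.shape[0], dtype=bool)
    return minor > min_minor_ac


def subset_windows(contigs: np.ndarray, positions: np.ndarray,
                   contig_lengths: Mapping[str, int], n_windows: int,
                   window_bp: int = 200, seed: int = 0) -> np.ndarray:
    """Boolean mask keeping sites inside ``n_windows`` random non-overlapping
    windows of ``window_bp``, mimicking reduced-representation (RADseq-like)
    site subsets.  Windows are allocated across contigs proportionally to
    length and drawn on a non-overlapping ``window_bp`` grid.
    """
    labels = list(contig_lengths)
    slots = {lab: contig_lengths[lab] // window_bp for lab in labels}
    total_slots = sum(slots.values())
    if n_windows > total_slots:
        raise ValueError(
            f"{n_windows} windows x {window_bp} bp exceed the genome span "
            f"({total_slots} windows available)")
    rng = np.random.default_rng(seed)

    # largest-remainder allocation proportional to contig length
    quota = {lab: n_windows * slots[lab] / total_slots for lab in labels}
    alloc = {lab: int(np.floor(quota[lab])) for lab in labels}
    short = n_windows - sum(alloc.values())
    for lab in sorted(labels, key=lambda L: quota[L] - alloc[L], reverse=True):
        if short == 0:
            break
        if alloc[lab] < slots[lab]:
            alloc[lab] += 1
            short -= 1

    mask = np.zeros(positions.shape[0], dtype=bool)
    for lab in labels:
        if alloc[lab] == 0:
            continue
        chosen = rng.choice(slots[lab], size=alloc[lab], replace=False)
        sel = contigs == lab
        slot_of_site = (positions[sel] - 1) // window_bp
        mask[sel] = np.isin(slot_of_site, chosen)
    return mask
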