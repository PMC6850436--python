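"""Pairwise genotype-category counts and the ratio statistics computed from them.

At any diallelic site a pair of diploid individuals carries one of nine
genotype combinations: each individual has 0, 1 or 2 copies of one of the two
alleles.  Tallied over the genome these nine counts (cells ``a`` through ``i``
of a 3x3 matrix, rows = individual 1, columns = individual 2) fully summarise
the pair's IBS-sharing pattern, and several relatedness statistics are simple
ratios of cell aggregates:

* ``R0 = (C+G)/E`` -- opposing homozygotes over double heterozygotes,
* ``R1 = E/(B+C+D+F+G+H)`` -- double heterozygotes over all discordant sites,
* KING-robust kinship ``(E - 2(C+G)) / (B+D+F+H+2E)``,
* fractions IBS0 ``(C+G)/total`` and IBS2 ``(A+E+I)/total``,
* Lee's relatedness-test statistic ``E/(C+G+E)`` (2/3 for unrelated pairs
  from one homogeneous population).

None of these requires population allele frequencies, which is what makes
them usable for pairs of individuals analysed in isolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


class RelatednessWarning(UserWarning):
    """Warning category for degenerate inputs (zero denominators etc.)."""


#: Cell names in row-major order; rows index the genotype of individual 1,
#: columns the genotype of individual 2 (0, 1 or 2 copies of one allele).
CELL_NAMES = ("a", "b", "c", "d", "e", "f", "g", "h", "i")

#: Sentinel for a missing genotype in integer-coded genotype vectors.
MISSING = -1


def _warn(msg: str) -> None:
    warnings.warn(msg, RelatednessWarning, stacklevel=3)


@dataclass(frozen=True)
class CategoryCounts:
    """The nine pairwise genotype-category counts (or proportions).

    ``matrix[g1, g2]`` holds the count of sites where individual 1 carries
    ``g1`` and individual 2 carries ``g2`` copies of the counted allele.
    Which allele is counted is immaterial: every statistic defined on these
    cells is invariant under allele relabeling (180-degree rotation of the
    matrix) and under swapping the two individuals (transposition).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"category matrix must be 3x3, got {m.shape}")
        if (m < 0).any():
            raise ValueError("category counts must be non-negative")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_cells(cls, a=0.0, b=0.0, c=0.0, d=0.0, e=0.0, f=0.0, g=0.0,
                   h=0.0, i=0.0) -> "CategoryCounts":
        return cls(np.array([[a, b, c], [d, e, f], [g, h, i]], dtype=float))

    @classmethod
    def zeros(cls) -> "CategoryCounts":
        return cls(np.zeros((3, 3)))

    # -- cell accessors ----------------------------------------------------
    @property
    def a(self) -> float: return float(self.matrix[0, 0])
    @property
    def b(self) -> float: return float(self.matrix[0, 1])
    @property
    def c(self) -> float: return float(self.matrix[0, 2])
    @property
    def d(self) -> float: return float(self.matrix[1, 0])
    @property
    def e(self) -> float: return float(self.matrix[1, 1])
    @property
    def f(self) -> float: return float(self.matrix[1, 2])
    @property
    def g(self) -> float: return float(self.matrix[2, 0])
    @property
    def h(self) -> float: return float(self.matrix[2, 1])
    @property
    def i(self) -> float: return float(self.matrix[2, 2])

    @property
    def n_sites(self) -> float:
        """Total mass: sum of all nine cells (exactly rounded, so it is
        invariant to cell reordering)."""
        return math.fsum(self.matrix.ravel())

    # -- aggregates the statistics consume ---------------------------------
    @property
    def opposing_homozygotes(self) -> float:
        """C + G: sites where the pair carries opposite homozygotes."""
        return self.c + self.g

    @property
    def het_het(self) -> float:
        """E: sites where both individuals are heterozygous."""
        return self.e

    @property
    def het_hom(self) -> float:
        """B + D + F + H: sites with one heterozygote and one homozygote.

        Exactly-rounded summation keeps the aggregate bit-identical under
        allele relabeling and individual swap.
        """
        return math.fsum((self.b, self.d, self.f, self.h))

    @property
    def hom_same(self) -> float:
        """A + I: sites where both carry the same homozygote."""
        return self.a + self.i

    # -- symmetries --------------------------------------------------------
    def relabel_alleles(self) -> "CategoryCounts":
        """Swap which allele is counted (a<->i, b<->h, c<->g, d<->f)."""
        return CategoryCounts(np.flip(self.matrix, axis=(0, 1)).copy())

    def swap_individuals(self) -> "CategoryCounts":
        """Exchange the roles of the two individuals (transpose)."""
        return CategoryCounts(self.matrix.T.copy())

    # -- arithmetic (used for pooling and leave-one-out) -------------------
    def __add__(self, other: "CategoryCounts") -> "CategoryCounts":
        return CategoryCounts(self.matrix + other.matrix)

    def __sub__(self, other: "CategoryCounts") -> "CategoryCounts":
        diff = self.matrix - other.matrix
        # tolerate tiny negative residue from float pooling
        diff = np.where(np.abs(diff) < 1e-9, np.maximum(diff, 0.0), diff)
        return CategoryCounts(diff)

    def normalized(self) -> "CategoryCounts":
        tot = self.n_sites
        if tot == 0:
            raise ValueError("cannot normalize empty CategoryCounts")
        return CategoryCounts(self.matrix / tot)

    def as_dict(self) -> Mapping[str, float]:
        return dict(zip(CELL_NAMES, self.matrix.ravel()))


@dataclass(frozen=True)
class KCoefficients:
    """IBD-sharing coefficients (k0, k1, k2) for a relationship category.

    k0, k1, k2 are the genome fractions where the pair shares 0, 1 or 2
    alleles identical by descent; they sum to one and define the kinship
    coefficient ``theta = k1/4 + k2/2``.
    """

    k0: float
    k1: float
    k2: float
    label: str = ""

    def __post_init__(self) -> None:
        ks = (self.k0, self.k1, self.k2)
        if any(k < 0 or k > 1 for k in ks):
            raise ValueError(f"k coefficients must lie in [0,1], got {ks}")
        if abs(sum(ks) - 1.0) > 1e-9:
            raise ValueError(f"k coefficients must sum to 1, got {ks}")

    @property
    def theta(self) -> float:
        return self.k1 / 4.0 + self.k2 / 2.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k0, self.k1, self.k2)


#: Expected (k0, k1, k2) for the close-relationship categories:
#: PO parent-offspring, FS full siblings, HS half-sibling/avuncular/
#: grandparent-grandchild (2nd degree), C1 first cousins, UR unrelated.
RELATIONSHIPS: Mapping[str, KCoefficients] = {
    "PO": KCoefficients(0.0, 1.0, 0.0, "PO"),
    "FS": KCoefficients(0.25, 0.5, 0.25, "FS"),
    "HS": KCoefficients(0.5, 0.5, 0.0, "HS"),
    "C1": KCoefficients(0.75, 0.25, 0.0, "C1"),
    "UR": KCoefficients(1.0, 0.0, 0.0, "UR"),
}


def theta_from_k(k: KCoefficients) -> float:
    """Kinship coefficient theta = k1/4 + k2/2."""
    return k.theta


def count_pair_matrix(genotypes_1: Iterable, genotypes_2: Iterable) -> CategoryCounts:
    """Tally the 3x3 genotype-pair matrix from two genotype vectors.

    Genotypes are coded 0/1/2 = copies of an (arbitrary) counted allele;
    missing genotypes may be given as -1, None or NaN.  Only sites where both
    individuals are non-missing contribute.

    Parameters
    ----------
    genotypes_1, genotypes_2
        Equal-length sequences of {0, 1, 2, missing}.
    """
    g1 = _coerce_genotypes(genotypes_1)
    g2 = _coerce_genotypes(genotypes_2)
    if g1.shape != g2.shape:
        raise ValueError(
            f"genotype vectors differ in length: {g1.size} vs {g2.size}")
    valid = (g1 >= 0) & (g2 >= 0)
    if not valid.any():
        _warn("no sites with both genotypes non-missing; returning zeros")
        return CategoryCounts.zeros()
    idx = 3 * g1[valid] + g2[valid]
    cells = np.bincount(idx, minlength=9).astype(float)
    return CategoryCounts(cells.reshape(3, 3))


def _coerce_genotypes(g: Iterable) -> np.ndarray:
    arr = np.asarray(list(g) if not isinstance(g, np.ndarray) else g)
    if arr.dtype == object or arr.dtype.kind == "f":
        out = np.full(arr.shape, MISSING, dtype=np.int64)
        for j, v in enumerate(arr.ravel()):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            out.ravel()[j] = int(v)
        arr = out
    arr = arr.astype(np.int64, copy=False)
    bad = (arr > 2) | ((arr < 0) & (arr != MISSING))
    if bad.any():
        raise ValueError(
            f"genotypes must be 0/1/2/missing; found value {arr[bad][0]}")
    return arr


# ---------------------------------------------------------------------------
# Ratio statistics
# ---------------------------------------------------------------------------

def _ratio(num: float, den: float, name: str) -> float:
    if den <= 0:
        _warn(f"{name}: zero denominator; returning NaN")
        return float("nan")
    return num / den


def r0(counts: CategoryCounts) -> float:
    """R0 = (C+G)/E.  Near 0 for parent-offspring, 0.5 for unrelated pairs
    from one homogeneous population, above 0.5 across populations."""
    return _ratio(counts.opposing_homozygotes, counts.het_het, "r0")


def r1(counts: CategoryCounts) -> float:
    """R1 = E/(B+C+D+F+G+H): double heterozygotes over all sites where the
    two genotypes differ in at least one allele."""
    den = counts.het_hom + counts.opposing_homozygotes
    return _ratio(counts.het_het, den, "r1")


def king_kinship(counts: CategoryCounts) -> float:
    """KING-robust kinship (E - 2(C+G)) / (B+D+H+F+2E).

    Approximates the kinship coefficient theta for non-inbred pairs from a
    homogeneous population; can be arbitrarily negative for cross-population
    pairs.
    """
    num = counts.het_het - 2.0 * counts.opposing_homozygotes
    den = counts.het_hom + 2.0 * counts.het_het
    if den <= 0:
        _warn("king_kinship: zero denominator; returning NaN")
        return float("nan")
    return num / den


def ibs_fractions(counts: CategoryCounts) -> tuple[float, float]:
    """(Fraction IBS0, Fraction IBS2) = ((C+G)/total, (A+E+I)/total).

    Unlike the ratio statistics these depend strongly on SNP ascertainment.
    """
    tot = counts.n_sites
    if tot <= 0:
        _warn("ibs_fractions: no sites; returning NaN")
        return (float("nan"), float("nan"))
    ibs0 = counts.opposing_homozygotes / tot
    ibs2 = math.fsum((counts.a, counts.e, counts.i)) / tot
    return (ibs0, ibs2)


def lee_statistic(counts: CategoryCounts) -> float:
    """Lee's relatedness-test statistic E/(C+G+E); expectation 2/3 for
    unrelated non-inbred pairs from the same homogeneous population."""
    den = counts.opposing_homozygotes + counts.het_het
    return _ratio(counts.het_het, den, "lee")


@dataclass
class PairStats:
    """All six pairwise statistics, with optional jackknife standard errors."""

    r0: float
    r1: float
    king_kinship: float
    ibs0: float
    ibs2: float
    lee: float
    n_sites: float
    se: dict[str, float] = field(default_factory=dict)

    STAT_NAMES = ("r0", "r1", "king_kinship", "ibs0", "ibs2", "lee")

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in self.STAT_NAMES}
        d["n_sites"] = self.n_sites
        for name, se in self.se.items():
            d[f"se_{name}"] = se
        return d


#: Statistic name -> function, for generic (e.g. jackknife) evaluation.
STATISTICS = {
    "r0": r0,
    "r1": r1,
    "king_kinship": king_kinship,
    "ibs0": lambda c: ibs_fractions(c)[0],
    "ibs2": lambda c: ibs_fractions(c)[1],
    "lee": lee_statistic,
}


def pair_stats(counts: CategoryCounts) -> PairStats:
    """Compute all six statistics from one category-count matrix."""
    ibs0, ibs2 = ibs_fractions(counts)
    return PairStats(
        r0=r0(counts),
        r1=r1(counts),
        king_kinship=king_kinship(counts),
        ibs0=ibs0,
        ibs2=ibs2,
        lee=lee_statistic(counts),
        n_sites=counts.n_sites,
    )
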