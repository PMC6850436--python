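"""Expected genotype-pair probabilities and attainable expectation ranges.

For a non-inbred pair sharing 0, 1 or 2 alleles IBD at a site with allele
frequency ``p``, the conditional genotype-pair probabilities have closed
forms (independence, one shared allele, identical genotypes).  Averaging the
IBD-0/1/2 matrices with weights (k0, k1, k2) and integrating over an allele
frequency spectrum gives the expected cell probabilities for any
relationship, and hence the expected value of every ratio statistic.

Because each expected cell is *linear* in the spectrum, every ratio
statistic's expectation is a linear-fractional function of the spectrum
weights; its extremes over all possible spectra are therefore attained at
point-mass spectra, and the attainable region in a joint plane such as
(R1, R0) is traced out by single frequencies and two-point mixtures.  This
is what allows relationship categories to be separated regardless of the
(unknown) allele frequency spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import CategoryCounts, KCoefficients, king_kinship, r0, r1


# ---------------------------------------------------------------------------
# Allele frequency spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumModel:
    """A discrete allele-frequency spectrum: support ``p`` with weights ``w``.

    Frequencies must lie strictly inside (0, 1); weights are normalized to
    sum to one.  A folded spectrum (all p <= 0.5) is a valid input anywhere a
    spectrum is consumed, since every statistic here is invariant to allele
    relabeling (p <-> 1-p).
    """

    p: np.ndarray
    w: np.ndarray
    name: str = "grid"

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if p.shape != w.shape:
            raise ValueError("p and w must have the same shape")
        if p.size == 0:
            raise ValueError("spectrum support is empty")
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("allele frequencies must lie strictly in (0,1)")
        if (w < 0).any():
            raise ValueError("spectrum weights must be non-negative")
        tot = w.sum()
        if tot <= 0:
            raise ValueError("spectrum weights sum to zero")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "w", w / tot)

    # -- constructors ------------------------------------------------------
    @classmethod
    def point_mass(cls, p: float) -> "SpectrumModel":
        return cls(np.array([p]), np.array([1.0]), name=f"point({p})")

    @classmethod
    def empirical(cls, ps: Sequence[float]) -> "SpectrumModel":
        ps = np.asarray(ps, dtype=float)
        vals, counts = np.unique(ps, return_counts=True)
        return cls(vals, counts.astype(float), name="empirical")

    @classmethod
    def neutral_constant(cls, n_chromosomes: int = 40,
                         tilt: float = 1.0, name: str | None = None
                         ) -> "SpectrumModel":
        """Expected SFS of a constant-size neutral population on a reference
        sample of ``n_chromosomes``: weight of derived count j proportional
        to 1/j (``tilt`` != 1 raises/lowers the rare-variant excess:
        weights proportional to j**-tilt)."""
        j = np.arange(1, n_chromosomes)
        w = j.astype(float) ** (-tilt)
        return cls(j / n_chromosomes, w,
                   name=name or f"neutral(n={n_chromosomes},tilt={tilt})")

    @classmethod
    def beta(cls, alpha: float, beta: float, n_grid: int = 512
             ) -> "SpectrumModel":
        from scipy import stats
        p = (np.arange(n_grid) + 0.5) / n_grid
        w = stats.beta.pdf(p, alpha, beta)
        return cls(p, w, name=f"beta({alpha},{beta})")

    @classmethod
    def folded(cls, p: Sequence[float], w: Sequence[float]) -> "SpectrumModel":
        """Build from a folded representation (p <= 0.5), unfolding
        symmetrically onto p and 1-p."""
        p = np.asarray(p, dtype=float)
        w = np.asarray(w, dtype=float)
        if (p > 0.5).any():
            raise ValueError("folded spectrum requires p <= 0.5")
        keep = p < 0.5
        p_full = np.concatenate([p, 1.0 - p[keep]])
        w_full = np.concatenate([w, w[keep]]) / 2.0
        return cls(p_full, w_full, name="folded-grid")

    # -- use ---------------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` per-site allele frequencies from the spectrum."""
        idx = rng.choice(self.p.size, size=size, p=self.w)
        return self.p[idx]

    def mean_over(self, values: np.ndarray) -> float:
        """Spectrum average of per-frequency values aligned with ``self.p``."""
        return float(np.dot(self.w, values))


#: The three demography scenarios used throughout: a constant-size
#: population, a recent 10-fold expansion (rare-variant excess) and a recent
#: 10-fold decline (common-variant excess).  Expansion/decline are
#: qualitative tilts of the neutral 1/j spectrum, not exact coalescent
#: expectations.
DEMOGRAPHY_TILT = {"constant": 1.0, "expansion": 1.5, "decline": 0.5}


def demography_spectrum(name: str, n_chromosomes: int = 40) -> SpectrumModel:
    """Spectrum for one of the named demographic scenarios
    ('constant', 'expansion', 'decline')."""
    try:
        tilt = DEMOGRAPHY_TILT[name]
    except KeyError:
        raise ValueError(
            f"unknown demography {name!r}; choose from {sorted(DEMOGRAPHY_TILT)}")
    return SpectrumModel.neutral_constant(n_chromosomes, tilt=tilt, name=name)


# ---------------------------------------------------------------------------
# Conditional and expected cell probabilities
# ---------------------------------------------------------------------------

def ibd_conditional_cells(p: float | np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype-pair probability matrices conditional on IBD state 0, 1, 2.

    For scalar ``p`` returns three 3x3 matrices (rows = genotype of
    individual 1, columns = individual 2); for an array of frequencies the
    matrices have shape ``(..., 3, 3)``.

    * IBD 0: genotypes independent, each Hardy-Weinberg.
    * IBD 1: one shared allele; the two remaining alleles are free draws.
    * IBD 2: identical genotypes, Hardy-Weinberg on the diagonal.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("allele frequency must lie strictly in (0,1)")
    q = 1.0 - p
    hw = np.stack([q * q, 2 * p * q, p * p], axis=-1)  # (..., 3)

    m0 = hw[..., :, None] * hw[..., None, :]

    z = np.zeros_like(p)
    m1 = np.stack([
        np.stack([q ** 3, p * q * q, z], axis=-1),
        np.stack([p * q * q, p * q, p * p * q], axis=-1),
        np.stack([z, p * p * q, p ** 3], axis=-1),
    ], axis=-2)

    m2 = np.zeros(p.shape + (3, 3))
    for g in range(3):
        m2[..., g, g] = hw[..., g]

    return m0, m1, m2


def expected_cells(k: KCoefficients, spectrum: SpectrumModel) -> CategoryCounts:
    """Expected cell probabilities for relationship ``k`` under ``spectrum``.

    Returns a :class:`CategoryCounts` whose cells sum to one:
    ``sum_p w(p) * [k0*M0(p) + k1*M1(p) + k2*M2(p)]``.
    """
    m0, m1, m2 = ibd_conditional_cells(spectrum.p)
    mix = k.k0 * m0 + k.k1 * m1 + k.k2 * m2  # (n, 3, 3)
    cells = np.tensordot(spectrum.w, mix, axes=(0, 0))
    return CategoryCounts(cells)


def expected_stats(k: KCoefficients, spectrum: SpectrumModel
                   ) -> tuple[float, float, float]:
    """(E[R1], E[R0], E[kinship]) of the genome-wide ratio statistics, i.e.
    the statistics evaluated at the expected cell probabilities."""
    cells = expected_cells(k, spectrum)
    return (r1(cells), r0(cells), king_kinship(cells))


# ---------------------------------------------------------------------------
# Expectation ranges over all spectra
# ---------------------------------------------------------------------------

@dataclass
class ExpectationRange:
    """Attainable range of expected statistics for one relationship as the
    allele-frequency spectrum varies over all possibilities.

    ``joint_r1r0`` / ``joint_r1kin`` sample the attainable joint region
    (columns r1, r0 resp. r1, kinship) over single frequencies and all
    two-point mixtures of the grid; for PO both regions are the single
    points (0.5, 0) and (0.5, 0.25).
    """

    label: str
    r0_min: float
    r0_max: float
    r1_min: float
    r1_max: float
    kinship_min: float
    kinship_max: float
    joint_r1r0: np.ndarray = field(repr=False)
    joint_r1kin: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for lo, hi in ((self.r0_min, self.r0_max), (self.r1_min, self.r1_max),
                       (self.kinship_min, self.kinship_max)):
            if lo > hi + 1e-12:
                raise ValueError("range minimum exceeds maximum")


def default_grid(n: int = 512, p_min: float = 1e-3) -> np.ndarray:
    """Folded frequency grid on (0, 0.5] used for range computations."""
    return np.linspace(p_min, 0.5, n)


def _aggregates_per_p(k: KCoefficients, p_grid: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frequency expected (opposing-hom, het-het, het-hom) aggregates."""
    m0, m1, m2 = ibd_conditional_cells(p_grid)
    mix = k.k0 * m0 + k.k1 * m1 + k.k2 * m2  # (n, 3, 3)
    og = mix[:, 0, 2] + mix[:, 2, 0]
    ee = mix[:, 1, 1]
    hh = mix[:, 0, 1] + mix[:, 1, 0] + mix[:, 1, 2] + mix[:, 2, 1]
    return og, ee, hh


def expectation_range(k: KCoefficients, p_grid: np.ndarray | None = None,
                      n_mixture_alphas: int = 21,
                      pair_stride: int = 4) -> ExpectationRange:
    """Attainable expectation range of (R1, R0, kinship) for ``k`` over all
    allele-frequency spectra.

    The per-statistic extremes are exact on the grid: each expectation is a
    ratio of spectrum-linear functionals, so its range over arbitrary
    mixtures equals its range over point masses.  The joint regions are
    sampled over all single grid frequencies plus all two-point mixtures of
    a strided sub-grid.
    """
    if p_grid is None:
        p_grid = default_grid()
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size == 0:
        raise ValueError("empty frequency grid")
    if p_grid.size < 100:
        raise ValueError("frequency grid needs at least 100 points")
    if ((p_grid <= 0) | (p_grid > 0.5)).any():
        raise ValueError("range grid must lie in (0, 0.5]")

    og, ee, hh = _aggregates_per_p(k, p_grid)

    with np.errstate(divide="ignore", invalid="ignore"):
        r0_p = og / ee
        r1_p = ee / (hh + og)
        kin_p = (ee - 2 * og) / (hh + 2 * ee)

    # two-point mixtures on a strided sub-grid
    sub = np.arange(0, p_grid.size, pair_stride)
    alphas = np.linspace(0.0, 1.0, n_mixture_alphas)
    og_s, ee_s, hh_s = og[sub], ee[sub], hh[sub]
    # (n_pairs_i, n_pairs_j, n_alpha) via broadcasting
    a = alphas[None, None, :]
    og_mix = a * og_s[:, None, None] + (1 - a) * og_s[None, :, None]
    ee_mix = a * ee_s[:, None, None] + (1 - a) * ee_s[None, :, None]
    hh_mix = a * hh_s[:, None, None] + (1 - a) * hh_s[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r0_m = (og_mix / ee_mix).ravel()
        r1_m = (ee_mix / (hh_mix + og_mix)).ravel()
        kin_m = ((ee_mix - 2 * og_mix) / (hh_mix + 2 * ee_mix)).ravel()

    r1_all = np.concatenate([r1_p, r1_m])
    r0_all = np.concatenate([r0_p, r0_m])
    kin_all = np.concatenate([kin_p, kin_m])
    ok = np.isfinite(r1_all) & np.isfinite(r0_all) & np.isfinite(kin_all)

    return ExpectationRange(
        label=k.label or "?",
        r0_min=float(np.nanmin(r0_p)), r0_max=float(np.nanmax(r0_p)),
        r1_min=float(np.nanmin(r1_p)), r1_max=float(np.nanmax(r1_p)),
        kinship_min=float(np.nanmin(kin_p)), kinship_max=float(np.nanmax(kin_p)),
        joint_r1r0=np.column_stack([r1_all[ok], r0_all[ok]]),
        joint_r1kin=np.column_stack([r1_all[ok], kin_all[ok]]),
    )
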