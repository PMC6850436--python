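"""Maximum-likelihood estimation of the pairwise genotype categories from
genotype likelihoods.

At low sequencing depth genotypes cannot be called reliably, but the
expected number of sites in each genotype-pair category can still be
estimated by treating the per-site category as a latent mixture label and
the genotype likelihoods as emission probabilities:

``L = prod_sites sum_categories pi_cat * GL1(g1_cat) * GL2(g2_cat)``

Two parameterisations are provided.  The SFS-based estimator works on
3-genotype likelihoods at diallelic sites with a designated known allele and
directly estimates the nine A-I categories (the two-individual 2D site
frequency spectrum).  The IBS-based estimator needs no known allele: it works
on all 10 possible diploid genotypes per individual and estimates all 100
genotype-pair categories, which are then collapsed onto A-I (pairs involving
more than two distinct alleles are discarded).  Both use plain EM, which for
this complete-data-multinomial mixture increases the likelihood every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .core import CategoryCounts, RelatednessWarning

#: Canonical base ordering.
BASES = "ACGT"

#: The 10 unordered diploid genotypes over {A,C,G,T}, lexicographic.
GENOTYPES10: tuple[tuple[int, int], ...] = tuple(
    (x, y) for x in range(4) for y in range(x, 4)
)
GENOTYPE10_NAMES = tuple(BASES[x] + BASES[y] for x, y in GENOTYPES10)

#: pair of base indices -> index into GENOTYPES10
PAIR_INDEX = np.full((4, 4), -1, dtype=np.int64)
for _k, (_x, _y) in enumerate(GENOTYPES10):
    PAIR_INDEX[_x, _y] = _k
    PAIR_INDEX[_y, _x] = _k

#: Number of sites below which per-contig EM chunks are warned about: with
#: little data per chunk the IBS0 count is biased upward relative to a
#: single joint run.
SMALL_CHUNK_SITES = 5000


def _warn(msg: str) -> None:
    warnings.warn(msg, RelatednessWarning, stacklevel=3)


@dataclass
class GLData:
    """A stream of per-site genotype likelihoods for one pair of individuals.

    ``gl1``/``gl2`` are (n_sites, 3) in ``diallelic3`` mode (likelihood of
    carrying 0/1/2 copies of the non-designated allele) or (n_sites, 10) in
    ``tengenotype10`` mode (one column per unordered base pair, see
    :data:`GENOTYPE10_NAMES`).  Likelihood vectors are linear-scale and
    scale-free: rescaling any site's vector leaves every estimate unchanged.
    ``contigs`` labels each site with its chromosome/contig for chunked
    estimation and jackknife blocking.
    """

    mode: str
    gl1: np.ndarray
    gl2: np.ndarray
    contigs: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        width = {"diallelic3": 3, "tengenotype10": 10}.get(self.mode)
        if width is None:
            raise ValueError(f"unknown GL mode {self.mode!r}")
        gl1 = np.asarray(self.gl1, dtype=float)
        gl2 = np.asarray(self.gl2, dtype=float)
        if gl1.shape != gl2.shape or gl1.ndim != 2 or gl1.shape[1] != width:
            raise ValueError(
                f"expected two (n,{width}) likelihood arrays, got "
                f"{gl1.shape} and {gl2.shape}")
        if (gl1 < 0).any() or (gl2 < 0).any():
            raise ValueError("genotype likelihoods must be non-negative")
        if (gl1.max(axis=1) <= 0).any() or (gl2.max(axis=1) <= 0).any():
            raise ValueError("each site needs at least one positive likelihood")
        self.gl1, self.gl2 = gl1, gl2
        if self.contigs is not None:
            self.contigs = np.asarray(self.contigs)
            if self.contigs.shape[0] != gl1.shape[0]:
                raise ValueError("contig labels must match number of sites")

    @property
    def n_sites(self) -> int:
        return self.gl1.shape[0]

    def subset(self, mask: np.ndarray) -> "GLData":
        return GLData(
            self.mode, self.gl1[mask], self.gl2[mask],
            None if self.contigs is None else self.contigs[mask],
            None if self.positions is None else self.positions[mask],
        )

    def by_contig(self) -> Iterator[tuple[object, "GLData"]]:
        if self.contigs is None:
            raise ValueError("GLData has no contig labels")
        for label in _unique_in_order(self.contigs):
            yield label, self.subset(self.contigs == label)


def _unique_in_order(labels: np.ndarray) -> list:
    seen: dict = {}
    for x in labels:
        seen.setdefault(x if not isinstance(x, np.generic) else x.item(), None)
    return list(seen)


@dataclass
class MixtureEstimate:
    """EM estimate of the category proportions for one pair.

    ``proportions`` has 9 entries (A-I, row-major) in SFS mode or 100
    entries (individual-1 genotype major) in IBS mode; ``counts`` is
    ``proportions * n_sites``, the expected number of sites per category.
    """

    mode: str
    proportions: np.ndarray
    n_sites: int
    log_likelihood: float
    n_iterations: int
    converged: bool
    ll_trace: np.ndarray = field(repr=False, default=None)

    @property
    def counts(self) -> np.ndarray:
        return self.proportions * self.n_sites

    def to_category_counts(self) -> CategoryCounts:
        """A-I expected counts (SFS mode only; use :func:`collapse_ibs` for
        IBS-mode estimates)."""
        if self.mode != "diallelic3":
            raise ValueError("use collapse_ibs() for tengenotype10 estimates")
        return CategoryCounts(self.counts.reshape(3, 3))


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def component_likelihoods(records: GLData) -> np.ndarray:
    """Per-site mixture-component likelihoods: the outer product of the two
    individuals' GL vectors, flattened to (n, 9) or (n, 100) and scaled to
    max 1 per site."""
    n = records.n_sites
    K = records.gl1.shape[1] ** 2
    P = (records.gl1[:, :, None] * records.gl2[:, None, :]).reshape(n, K)
    return P / P.max(axis=1, keepdims=True)


def _run_em(P: np.ndarray, tol: float, max_iter: int,
            pi0: np.ndarray | None = None
            ) -> tuple[np.ndarray, float, int, bool, np.ndarray]:
    """EM for a K-component multinomial mixture with fixed per-site component
    likelihoods ``P`` (n x K, each row scaled to max 1).

    Iterates pi_k <- pi_k * mean_s [ P[s,k] / sum_j pi_j P[s,j] ] from a
    uniform start until the largest proportion change drops below ``tol``.
    The stopping rule is on the proportions, not the log-likelihood gain:
    components whose true proportion is zero decay geometrically and keep
    producing negligible likelihood gains long before the proportions have
    reached the boundary, and a likelihood-gain rule is additionally
    scale-dependent in the number of sites.
    """
    n, K = P.shape
    pi = np.full(K, 1.0 / K) if pi0 is None else np.asarray(pi0, dtype=float)
    # a warm start must keep every component reachable: the multiplicative
    # update can never revive an exactly-zero proportion
    pi = np.maximum(pi, 1e-12)
    pi = pi / pi.sum()
    ll_trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = P @ pi  # (n,)
        ll = float(np.log(w).sum())
        ll_trace.append(ll)
        resp_sum = P.T @ (1.0 / w)  # (K,)
        pi_new = pi * resp_sum / n
        pi_new /= pi_new.sum()  # guard rounding drift
        delta = float(np.abs(pi_new - pi).max())
        pi = pi_new
        if delta < tol:
            converged = True
            break
    # final likelihood at the returned proportions
    ll = float(np.log(P @ pi).sum())
    ll_trace.append(ll)
    return pi, ll, it, converged, np.asarray(ll_trace)


def _prepare(P: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale each site's likelihood row to max 1; report whether every row is
    flat (completely uninformative input)."""
    P = P / P.max(axis=1, keepdims=True)
    flat = bool((P.min(axis=1) == 1.0).all())
    return P, flat


def em_sfs2d(records: GLData, tol: float = 1e-8, max_iter: int = 2000
             ) -> MixtureEstimate:
    """SFS-based estimator: EM over the nine A-I categories from 3-genotype
    likelihoods (requires a designated allele per site)."""
    if records.mode != "diallelic3":
        raise ValueError("em_sfs2d requires diallelic3 GLData")
    n = records.n_sites
    P, flat = _prepare(component_likelihoods(records))
    if flat:
        _warn("all genotype likelihoods are flat; returning uniform proportions")
        pi = np.full(9, 1.0 / 9.0)
        ll = float(np.log(P @ pi).sum())
        return MixtureEstimate("diallelic3", pi, n, ll, 0, False,
                               np.array([ll]))
    pi, ll, it, conv, trace = _run_em(P, tol, max_iter)
    if not conv:
        _warn(f"em_sfs2d did not converge within {max_iter} iterations")
    return MixtureEstimate("diallelic3", pi, n, ll, it, conv, trace)


def em_ibs(records: GLData, tol: float = 1e-8, max_iter: int = 2000
           ) -> MixtureEstimate:
    """IBS-based estimator: EM over all 100 genotype-pair categories from
    10-genotype likelihoods (no known allele needed)."""
    if records.mode != "tengenotype10":
        raise ValueError("em_ibs requires tengenotype10 GLData")
    n = records.n_sites
    P, flat = _prepare(component_likelihoods(records))
    if flat:
        _warn("all genotype likelihoods are flat; returning uniform proportions")
        pi = np.full(100, 0.01)
        ll = float(np.log(P @ pi).sum())
        return MixtureEstimate("tengenotype10", pi, n, ll, 0, False,
                               np.array([ll]))
    pi, ll, it, conv, trace = _run_em(P, tol, max_iter)
    if not conv:
        _warn(f"em_ibs did not converge within {max_iter} iterations")
    return MixtureEstimate("tengenotype10", pi, n, ll, it, conv, trace)


# ---------------------------------------------------------------------------
# Collapse of the 100 genotype-pair categories onto A-I
# ---------------------------------------------------------------------------

def _collapse_matrix() -> tuple[np.ndarray, np.ndarray]:
    """(100 x 9) mapping of genotype-pair mass onto A-I cells plus a (100,)
    discard mask for pairs whose allele union exceeds two bases.

    Only the four relabel-invariant aggregates are identifiable without an
    allele orientation, so mass is spread evenly across the cells of its
    aggregate (a/i, b/d/f/h, c/g); every statistic is invariant to this split.
    """
    M = np.zeros((100, 9))
    discard = np.zeros(100, dtype=bool)
    cell = {name: idx for idx, name in
            enumerate("abcdefghi")}
    for i1, (x1, y1) in enumerate(GENOTYPES10):
        for i2, (x2, y2) in enumerate(GENOTYPES10):
            kk = i1 * 10 + i2
            union = {x1, y1, x2, y2}
            if len(union) > 2:
                discard[kk] = True
                continue
            het1, het2 = x1 != y1, x2 != y2
            if not het1 and not het2:
                if x1 == x2:  # same homozygote: A or I
                    M[kk, cell["a"]] = M[kk, cell["i"]] = 0.5
                else:  # opposing homozygotes: C or G
                    M[kk, cell["c"]] = M[kk, cell["g"]] = 0.5
            elif het1 and het2:  # both het, same allele pair: E
                M[kk, cell["e"]] = 1.0
            else:  # het/hom sharing one allele: B, D, F or H
                for nm in ("b", "d", "f", "h"):
                    M[kk, cell[nm]] = 0.25
    return M, discard


COLLAPSE_MATRIX, DISCARD_MASK = _collapse_matrix()


def collapse_ibs(estimate: MixtureEstimate) -> tuple[CategoryCounts, float]:
    """Collapse a 100-category IBS estimate onto A-I expected counts.

    Returns ``(counts, discarded_fraction)`` where the discarded fraction is
    the estimated proportion of sites whose genotype pair involves more than
    two distinct alleles (these cannot be represented in a diallelic table).
    """
    if estimate.mode != "tengenotype10":
        raise ValueError("collapse_ibs requires a tengenotype10 estimate")
    counts = estimate.counts
    cells = counts @ COLLAPSE_MATRIX
    discarded = float(counts[DISCARD_MASK].sum() / max(counts.sum(), 1e-300))
    return CategoryCounts(cells.reshape(3, 3)), discarded


# ---------------------------------------------------------------------------
# Per-contig chunked estimation
# ---------------------------------------------------------------------------

@dataclass
class ChunkedEstimate:
    """Per-contig EM estimates plus their pooled A-I counts."""

    mode: str
    per_contig: dict
    per_contig_counts: dict
    pooled: CategoryCounts
    discarded_fraction: float = 0.0

    @property
    def block_counts(self) -> list[CategoryCounts]:
        return list(self.per_contig_counts.values())


def chunked_estimate(records: GLData, tol: float = 1e-8,
                     max_iter: int = 2000) -> ChunkedEstimate:
    """Run the EM separately per contig and pool the expected A-I counts.

    This bounds memory on genome-scale input and yields the per-chromosome
    counts the block jackknife needs.  With very small chunks at low depth
    the pooled IBS0 count is biased upward relative to a single joint run,
    so a warning is emitted when chunks are small.
    """
    estimates: dict = {}
    counts: dict = {}
    discarded_total = 0.0
    n_total = 0
    small = []
    for label, chunk in records.by_contig():
        if chunk.n_sites == 0:
            _warn(f"contig {label!r} has no sites; skipped")
            continue
        if chunk.n_sites < SMALL_CHUNK_SITES:
            small.append(label)
        if records.mode == "diallelic3":
            est = em_sfs2d(chunk, tol=tol, max_iter=max_iter)
            cc = est.to_category_counts()
        else:
            est = em_ibs(chunk, tol=tol, max_iter=max_iter)
            cc, disc = collapse_ibs(est)
            discarded_total += disc * chunk.n_sites
        estimates[label] = est
        counts[label] = cc
        n_total += chunk.n_sites
    if not estimates:
        raise ValueError("no contigs with data")
    if small:
        _warn(
            f"{len(small)} contig chunk(s) have fewer than "
            f"{SMALL_CHUNK_SITES} sites; per-chromosome estimation on small "
            "chunks inflates the IBS0 count relative to a single joint run")
    pooled = CategoryCounts(
        np.sum([c.matrix for c in counts.values()], axis=0))
    return ChunkedEstimate(records.mode, estimates, counts, pooled,
                           discarded_total / max(n_total, 1))


def hard_call_gls(genotypes: Sequence[int], mode: str = "diallelic3",
                  alleles: np.ndarray | None = None) -> np.ndarray:
    """One-hot ('hard call') likelihoods from known genotypes, mainly for
    validation: with these either EM reproduces plain genotype counting.

    For ``tengenotype10`` the per-site ref/alt base indices must be supplied
    via ``alleles`` (n x 2) so dosages can be placed among the 10 genotypes.
    """
    g = np.asarray(genotypes, dtype=np.int64)
    if mode == "diallelic3":
        out = np.zeros((g.size, 3))
        out[np.arange(g.size), g] = 1.0
        return out
    if alleles is None:
        raise ValueError("tengenotype10 hard calls need per-site alleles")
    ref, alt = alleles[:, 0], alleles[:, 1]
    lo = np.minimum(ref, alt)
    hi = np.maximum(ref, alt)
    idx = np.where(g == 0, PAIR_INDEX[ref, ref],
                   np.where(g == 2, PAIR_INDEX[alt, alt], PAIR_INDEX[lo, hi]))
    out = np.zeros((g.size, 10))
    out[np.arange(g.size), idx] = 1.0
    return out
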