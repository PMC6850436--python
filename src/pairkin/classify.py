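"""Relationship classification from the pairwise statistics.

Two independent schemes:

* ``classify_r1r0`` assigns the label of the nearest reference point in the
  (R1, R0) plane (Euclidean distance).  The shipped reference points were
  generated by this package's simulator under a constant-size-population
  spectrum with a fixed seed and can be regenerated with
  :func:`make_reference_points`.
* ``classify_kinship`` bands the KING-robust kinship estimate using the
  standard powers-of-two cut points (0.354, 0.177, 0.0884, 0.0442) plus a
  2^-13/2 floor that separates "unknown/distantly related" from unrelated;
  within the 1st-degree band, PO is separated from FS by R0 < 0.02
  (opposing homozygotes are essentially impossible for parent-offspring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .core import PairStats, KCoefficients, RELATIONSHIPS

#: Label returned when the required statistics are not finite.
UNCLASSIFIABLE = "unclassifiable"

#: Relatedness ordering used to break exact distance ties toward the less
#: related category.
_RELATEDNESS_ORDER = ("UR", "UK-DR", "C1", "HS", "FS", "PO", "DUP")


@dataclass(frozen=True)
class ReferencePoints:
    """Per-relationship (r1, r0) reference coordinates with provenance."""

    points: Mapping[str, tuple[float, float]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("need at least two reference points")


#: Reference points simulated from the constant-Ne spectrum
#: (SpectrumModel.neutral_constant(40), 10^6 sites per relationship,
#: seed 2019); regenerate with make_reference_points().
DEFAULT_REFERENCE_POINTS = ReferencePoints(
    points={
        "PO": (0.5017, 0.0),
        "FS": (0.67, 0.0751),
        "HS": (0.3387, 0.2048),
        "C1": (0.2817, 0.3326),
        "UR": (0.2291, 0.4966),
    },
    provenance="pairkin simulator, constant-Ne spectrum (40 chromosomes), "
               "1e6 sites per relationship, seed 2019",
)


def make_reference_points(seed: int = 2019, n_sites: int = 1_000_000
                          ) -> ReferencePoints:
    """Regenerate the (r1, r0) reference points from fresh simulations under
    the constant-size-population spectrum."""
    from .expectations import SpectrumModel
    from .simulate import PairSimConfig, simulate_pair_genotypes

    spectrum = SpectrumModel.neutral_constant(40)
    points = {}
    for idx, label in enumerate(("PO", "FS", "HS", "C1", "UR")):
        pair = simulate_pair_genotypes(PairSimConfig(
            relationship=label, n_sites=n_sites, spectrum=spectrum,
            seed=seed + idx))
        s = pair.stats()
        points[label] = (round(s.r1, 4), round(s.r0, 4))
    return ReferencePoints(
        points=points,
        provenance=f"pairkin simulator, constant-Ne spectrum (40 chromosomes), "
                   f"{n_sites} sites per relationship, seed {seed}")


@dataclass(frozen=True)
class KinshipThresholds:
    """Kinship band cut points (strictly decreasing) and the PO/FS R0 rule.

    Bands: kinship >= ``duplicate`` -> DUP (duplicate/monozygotic);
    >= ``first_degree`` -> PO or FS (split on ``po_fs_r0_cutoff``);
    >= ``second_degree`` -> HS; >= ``third_degree`` -> C1;
    >= ``floor`` -> UK-DR; below -> UR.
    """

    duplicate: float = 2.0 ** -1.5       # 0.3536
    first_degree: float = 2.0 ** -2.5    # 0.1768
    second_degree: float = 2.0 ** -3.5   # 0.0884
    third_degree: float = 2.0 ** -4.5    # 0.0442
    floor: float = 2.0 ** -6.5           # 0.0110 = 1/2^(13/2)
    po_fs_r0_cutoff: float = 0.02

    def __post_init__(self) -> None:
        cuts = (self.duplicate, self.first_degree, self.second_degree,
                self.third_degree, self.floor)
        if any(a <= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("kinship cut points must be strictly decreasing")


DEFAULT_THRESHOLDS = KinshipThresholds()


def _extract(stats: PairStats | tuple, attrs: tuple[str, ...]) -> tuple:
    if isinstance(stats, PairStats):
        return tuple(getattr(stats, a) for a in attrs)
    return tuple(stats)


def classify_r1r0(stats: PairStats | tuple[float, float],
                  refs: ReferencePoints = DEFAULT_REFERENCE_POINTS) -> str:
    """Label of the nearest reference point in the (r1, r0) plane.

    ``stats`` may be a :class:`PairStats` or a bare ``(r1, r0)`` pair.
    Exact distance ties break toward the less related category.
    """
    r1_, r0_ = _extract(stats, ("r1", "r0"))
    if not (math.isfinite(r1_) and math.isfinite(r0_)):
        return UNCLASSIFIABLE
    best_label, best_d = None, math.inf
    for label in sorted(refs.points,
                        key=lambda L: _RELATEDNESS_ORDER.index(L)
                        if L in _RELATEDNESS_ORDER else len(_RELATEDNESS_ORDER)):
        pr1, pr0 = refs.points[label]
        d = (r1_ - pr1) ** 2 + (r0_ - pr0) ** 2
        if d < best_d:  # ties keep the earlier (less related) label
            best_label, best_d = label, d
    return best_label


def classify_kinship(stats: PairStats | tuple[float, float],
                     thresholds: KinshipThresholds = DEFAULT_THRESHOLDS
                     ) -> str:
    """Relationship degree from kinship bands, with the 1st-degree band
    split into PO (r0 below the cutoff) and FS.

    ``stats`` may be a :class:`PairStats` or a bare ``(kinship, r0)`` pair.
    """
    kin, r0_ = _extract(stats, ("king_kinship", "r0"))
    if not math.isfinite(kin):
        return UNCLASSIFIABLE
    t = thresholds
    if kin >= t.duplicate:
        return "DUP"
    if kin >= t.first_degree:
        if not math.isfinite(r0_):
            return UNCLASSIFIABLE
        return "PO" if r0_ < t.po_fs_r0_cutoff else "FS"
    if kin >= t.second_degree:
        return "HS"
    if kin >= t.third_degree:
        return "C1"
    if kin > t.floor:
        return "UK-DR"
    return "UR"
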