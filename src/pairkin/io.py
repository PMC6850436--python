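"""Readers and writers: VCF genotypes/PL likelihoods, beagle-style GL text,
the package's 10-genotype GL table, and TSV result tables.

All writes are atomic (temp file in the destination directory, then rename),
so a crashed run never leaves a truncated output file behind.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING
from .gl import BASES, GLData, GENOTYPE10_NAMES

logger = logging.getLogger("pairkin")


@dataclass
class SiteTable:
    """Parsed site-level data for a set of individuals.

    ``genotypes`` (n_sites x n_samples, alt-allele dosage, -1 missing) and
    ``gls`` (list per sample of (n_sites, 3) linear-scale likelihoods) are
    each optional depending on the payload the source file carried.
    Positions are 1-based and strictly increasing within each contig.
    """

    samples: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray | None = None
    gls: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        for lab in dict.fromkeys(self.contigs):
            pos = self.positions[self.contigs == lab]
            if pos.size and not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on contig {lab!r}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(
                f"sample {name!r} not found; available: {self.samples}")

    def genotype_pair(self, s1: str, s2: str) -> tuple[np.ndarray, np.ndarray]:
        if self.genotypes is None:
            raise ValueError("site table carries no genotypes")
        return (self.genotypes[:, self.sample_index(s1)],
                self.genotypes[:, self.sample_index(s2)])

    def gl_pair(self, s1: str, s2: str) -> GLData:
        if self.gls is None:
            raise ValueError("site table carries no genotype likelihoods")
        return GLData("diallelic3", self.gls[self.sample_index(s1)],
                      self.gls[self.sample_index(s2)], self.contigs,
                      self.positions)


# ---------------------------------------------------------------------------
# Atomic writing
# ---------------------------------------------------------------------------

def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Atomically write a DataFrame as TSV."""
    atomic_write_text(path, df.to_csv(sep="\t", index=False,
                                      float_format="%.6g"))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, samples: Sequence[str] | None = None,
             payload: str = "GT") -> SiteTable:
    """Read biallelic SNP records from a VCF.

    ``payload`` is ``"GT"`` (dosages of the ALT allele vs REF, -1 missing),
    ``"PL"`` (phred-scaled likelihoods converted to linear scale) or
    ``"both"``.  Multi-allelic and non-SNP records are skipped and counted.
    """
    from cyvcf2 import VCF

    if payload not in ("GT", "PL", "both"):
        raise ValueError("payload must be 'GT', 'PL' or 'both'")
    vcf = VCF(str(path))
    available = list(vcf.samples)
    if samples is None:
        samples = available
    else:
        missing = [s for s in samples if s not in available]
        if missing:
            raise KeyError(
                f"sample(s) {missing} not in VCF; available: {available}")
        vcf.set_samples(list(samples))
        samples = list(vcf.samples)

    contigs, positions, refs, alts = [], [], [], []
    gts, pls = [], []
    n_skipped = 0
    want_gt = payload in ("GT", "both")
    want_pl = payload in ("PL", "both")
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        contigs.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        if want_gt:
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = np.array(v.gt_types)
            gts.append(np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2],
                                 default=MISSING))
        if want_pl:
            pl = v.format("PL")
            if pl is None:
                pls.append(np.ones((len(samples), 3)))
            else:
                pl = np.asarray(pl, dtype=float)
                pl = np.where((pl < 0) | ~np.isfinite(pl), 0.0, pl)
                pls.append(10.0 ** (-pl / 10.0))
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP record(s)",
                    n_skipped)
    if not positions:
        raise ValueError(f"no usable biallelic SNP records in {path}")

    genotypes = np.vstack(gts).astype(np.int64) if want_gt else None
    gls = None
    if want_pl:
        stack = np.stack(pls)  # (n_sites, n_samples, 3)
        gls = [np.ascontiguousarray(stack[:, j, :])
               for j in range(len(samples))]
    return SiteTable(list(samples), np.array(contigs), np.array(positions),
                     np.array(refs), np.array(alts), genotypes, gls)


def write_vcf(pair_or_table, path: str | Path,
              sample_names: Sequence[str] = ("ind1", "ind2")) -> None:
    """Write simulated pair genotypes as a minimal GT-only VCF."""
    from .simulate import SimulatedPair

    if not isinstance(pair_or_table, SimulatedPair):
        raise TypeError("write_vcf expects a SimulatedPair")
    pair = pair_or_table
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2"]
    for lab in dict.fromkeys(pair.contigs):
        lines.append(f"##contig=<ID={lab},length={pair.contig_lengths[lab]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names))
    for j in range(pair.n_sites):
        ref = BASES[pair.alleles[j, 0]]
        alt = BASES[pair.alleles[j, 1]]
        lines.append(
            f"{pair.contigs[j]}\t{pair.positions[j]}\t.\t{ref}\t{alt}\t.\t"
            f"PASS\t.\tGT\t{gt_str[int(pair.g1[j])]}\t{gt_str[int(pair.g2[j])]}")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# beagle-style 3-likelihood GL text
# ---------------------------------------------------------------------------

def write_beagle_gl(gl: GLData, path: str | Path,
                    alleles: np.ndarray | None = None,
                    sample_names: Sequence[str] = ("ind1", "ind2")) -> None:
    """Write diallelic 3-genotype likelihoods as beagle-style text: columns
    ``marker allele1 allele2`` then three likelihood columns per individual
    (major/major, major/minor, minor/minor); marker = ``contig_pos``."""
    if gl.mode != "diallelic3":
        raise ValueError("beagle output requires diallelic3 GLData")
    if gl.contigs is None or gl.positions is None:
        raise ValueError("beagle output requires contig/position metadata")
    if alleles is None:
        alleles = np.zeros((gl.n_sites, 2), dtype=int)
        alleles[:, 1] = 1
    header = ["marker", "allele1", "allele2"]
    for name in sample_names:
        header += [name] * 3
    rows = ["\t".join(header)]
    for j in range(gl.n_sites):
        fields = [f"{gl.contigs[j]}_{gl.positions[j]}",
                  str(int(alleles[j, 0])), str(int(alleles[j, 1]))]
        fields += [f"{x:.6g}" for x in gl.gl1[j]]
        fields += [f"{x:.6g}" for x in gl.gl2[j]]
        rows.append("\t".join(fields))
    atomic_write_text(path, "\n".join(rows) + "\n")


def read_beagle_gl(path: str | Path) -> SiteTable:
    """Read beagle-style GL text (see :func:`write_beagle_gl`) into a
    :class:`SiteTable` with 3-genotype likelihood payloads."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[1] < 6 or (df.shape[1] - 3) % 3 != 0:
        raise ValueError(
            f"beagle file needs 3 site columns plus 3 per individual; "
            f"got {df.shape[1]} columns")
    n_ind = (df.shape[1] - 3) // 3
    contigs, positions = [], []
    for lineno, marker in enumerate(df.iloc[:, 0], start=2):
        if "_" not in str(marker):
            raise ValueError(
                f"malformed marker {marker!r} on line {lineno}: expected "
                "'contig_position'")
        contig, _, pos = str(marker).rpartition("_")
        try:
            positions.append(int(pos))
        except ValueError:
            raise ValueError(
                f"malformed marker {marker!r} on line {lineno}: position "
                "is not an integer")
        contigs.append(contig)
    sample_names = []
    for j in range(n_ind):
        raw = df.columns[3 + 3 * j]
        sample_names.append(raw.split(".")[0])
    values = df.iloc[:, 3:].to_numpy(dtype=float)
    gls = [np.ascontiguousarray(values[:, 3 * j:3 * j + 3])
           for j in range(n_ind)]
    ref = df.iloc[:, 1].to_numpy()
    alt = df.iloc[:, 2].to_numpy()
    return SiteTable(sample_names, np.array(contigs), np.array(positions),
                     ref, alt, None, gls)


# ---------------------------------------------------------------------------
# 10-genotype GL table (package-defined dialect)
# ---------------------------------------------------------------------------

def write_gl10(gl: GLData, path: str | Path,
               sample_names: Sequence[str] = ("ind1", "ind2")) -> None:
    """Write 10-genotype likelihoods as TSV: ``contig pos`` then ten columns
    per individual named ``<sample>_<genotype>`` (AA, AC, ..., TT).  This
    layout is defined by this package; there is no community standard for
    10-genotype likelihood text."""
    if gl.mode != "tengenotype10":
        raise ValueError("gl10 output requires tengenotype10 GLData")
    cols = {"contig": gl.contigs, "pos": gl.positions}
    for name, arr in zip(sample_names, (gl.gl1, gl.gl2)):
        for k, gname in enumerate(GENOTYPE10_NAMES):
            cols[f"{name}_{gname}"] = arr[:, k]
    write_table(pd.DataFrame(cols), path)


def read_gl10(path: str | Path) -> GLData:
    """Read the package's 10-genotype GL TSV (two individuals)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 22:
        raise ValueError(
            f"gl10 table must have contig, pos and 2x10 likelihood columns; "
            f"got {df.shape[1]}")
    vals = df.iloc[:, 2:].to_numpy(dtype=float)
    return GLData("tengenotype10", vals[:, :10], vals[:, 10:],
                  df["contig"].to_numpy(), df["pos"].to_numpy())


# ---------------------------------------------------------------------------
# Genotype TSV
# ---------------------------------------------------------------------------

def write_genotype_tsv(pair_or_table, path: str | Path,
                       sample_names: Sequence[str] = ("ind1", "ind2")) -> None:
    """Write genotypes as TSV (contig, pos, ref, alt, one 0/1/2/NA column
    per individual)."""
    from .simulate import SimulatedPair

    pair = pair_or_table
    if not isinstance(pair, SimulatedPair):
        raise TypeError("write_genotype_tsv expects a SimulatedPair")
    df = pd.DataFrame({
        "contig": pair.contigs, "pos": pair.positions,
        "ref": [BASES[b] for b in pair.alleles[:, 0]],
        "alt": [BASES[b] for b in pair.alleles[:, 1]],
        sample_names[0]: pair.g1.astype(object),
        sample_names[1]: pair.g2.astype(object),
    })
    for name in sample_names:
        df[name] = df[name].where(df[name] != MISSING, "NA")
    write_table(df, path)


def read_genotype_tsv(path: str | Path) -> SiteTable:
    """Read a genotype TSV (contig, pos, ref, alt, then one 0/1/2/NA column
    per individual)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = ["contig", "pos", "ref", "alt"]
    if list(df.columns[:4]) != required:
        raise ValueError(
            f"genotype TSV must start with columns {required}; "
            f"got {list(df.columns[:4])}")
    sample_cols = list(df.columns[4:])
    if not sample_cols:
        raise ValueError("genotype TSV has no sample columns")
    geno = (df[sample_cols].replace("NA", MISSING).astype(float)
            .fillna(MISSING).astype(np.int64).to_numpy())
    return SiteTable(sample_cols, df["contig"].to_numpy(),
                     df["pos"].to_numpy(), df["ref"].to_numpy(),
                     df["alt"].to_numpy(), geno, None)
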