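"""Shared in-memory containers.

Coordinate conventions (package-wide): VCF positions are 1-based
inclusive, BED intervals 0-based half-open.  All internal interval
arithmetic is 0-based half-open; conversion happens only at the
parse/write boundary (see :mod:`phytomer.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class InternodeProfile:
    """One plant's ordered internode lengths, proximal (index 1) to distal (index n).

    Lengths are in centimetres.  ``axis_kind`` distinguishes the vegetative
    culm from the reproductive rachis.
    """

    plant_id: str
    genotype_id: str
    lengths: np.ndarray
    axis_kind: str = "culm"

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 1:
            raise ValueError("lengths must be a 1-D vector")
        if np.any(self.lengths <= 0):
            raise ValueError(
                f"profile {self.plant_id}: internode lengths must be positive"
            )
        if self.axis_kind not in ("culm", "rachis"):
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")

    @property
    def n(self) -> int:
        """Node count (number of internodes)."""
        return int(self.lengths.size)


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs with a chromosome/position map.

    ``dosage`` counts alt alleles per diploid accession (0/1/2); missing
    calls are ``NaN``.  Shape is ``(n_accessions, n_snps)``.  Positions are
    1-based and strictly increasing within a chromosome.
    """

    accession_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    snp_ids: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n_acc, n_snp = self.dosage.shape
        if len(self.accession_ids) != n_acc:
            raise ValueError("accession_ids length does not match dosage rows")
        if self.chrom.size != n_snp or self.pos.size != n_snp:
            raise ValueError("chrom/pos length does not match dosage columns")
        if self.snp_ids is None:
            self.snp_ids = np.array(
                [f"{c}_{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
            )
        else:
            self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or NaN (biallelic diploid)")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return int(hits[0])

    def subset_snps(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosage=self.dosage[:, idx],
            snp_ids=self.snp_ids[idx],
            ref=None if self.ref is None else self.ref[idx],
            alt=None if self.alt is None else self.alt[idx],
        )


@dataclass
class GraphicalGenotype:
    """Window x accession haplotype-group labels from sliding-window clustering.

    ``labels`` holds ``0`` for the major cluster, ``1`` for the minor one and
    ``-1`` where a window contains no SNP (``no_data``).
    """

    windows: pd.DataFrame  # columns: chrom, start, end, n_snps, single_cluster
    labels: np.ndarray  # (n_windows, n_accessions) int
    accession_ids: list[str]
    window_bp: int
    step_bp: int

    MAJOR: int = field(default=0, repr=False)
    MINOR: int = field(default=1, repr=False)
    NO_DATA: int = field(default=-1, repr=False)
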