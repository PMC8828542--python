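"""Diploid SNP dosage matrices and plain-text VCF input/output.

The container is deliberately simple: an ``individuals x sites`` float array
of allele dosages (0/1/2 of the alternate allele) with ``nan`` marking
missing calls, plus per-site metadata.  Reading uses :mod:`cyvcf2`; writing
emits minimal uncompressed VCF 4.2 with diploid ``GT`` fields (``./.`` for
missing) so panels round-trip through standard tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-sites dosage matrix.

    Attributes
    ----------
    dosages:
        ``(n_individuals, n_sites)`` float array with values in {0, 1, 2}
        or ``nan`` for missing calls.
    chrom, pos, ref, alt:
        Per-site metadata. Positions are strictly increasing within a
        chromosome.
    individual_ids:
        Sample names, length ``n_individuals``.
    truth:
        Optional simulator ground truth (ancestral frequencies,
        subpopulation labels, Balding–Nichols F, planted QTL).
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    individual_ids: list[str]
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be in {0, 1, 2} or nan")
        for name in ("chrom", "pos", "ref", "alt"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != self.n_sites:
                raise ValueError(f"{name} length {arr.shape[0]} != n_sites {self.n_sites}")
            setattr(self, name, arr)
        for c in np.unique(self.chrom):
            p = np.asarray(self.pos)[self.chrom == c]
            if p.size > 1 and not (np.diff(p.astype(np.int64)) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def site_ids(self) -> np.ndarray:
        """Marker names in ``chrom_pos`` form."""
        return np.array([f"{c}_{p}" for c, p in zip(self.chrom, self.pos)])

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-site alternate allele frequency among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-site mean."""
        out = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(out))
        out[idx] = col_mean[idx[1]]
        return out

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            individual_ids=list(self.individual_ids),
            truth=dict(self.truth),
        )


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path, truth_path: str | Path | None = None) -> None:
    """Write a plain-text VCF 4.2 with diploid GT fields; ``./.`` = missing.

    If ``truth_path`` is given, the matrix's simulator ground truth is
    serialized alongside as JSON.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rootpheno\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individual_ids) + "\n")
        ids = g.site_ids
        for j in range(g.n_sites):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in g.dosages[:, j]
            )
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{ids[j]}\t{g.ref[j]}\t{g.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )
    if truth_path is not None:
        with Path(truth_path).open("w") as fh:
            json.dump(_jsonable(g.truth), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic diploid genotypes from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # allele-level genotype arrays; -1 marks a missing allele
        arr = np.array(var.genotypes)[:, :2].astype(float)
        dose = arr.sum(axis=1)
        dose[(arr < 0).any(axis=1)] = np.nan
        rows.append(dose)
    return GenotypeMatrix(
        dosages=np.array(rows).T if rows else np.empty((len(samples), 0)),
        chrom=np.array(chrom),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref),
        alt=np.array(alt),
        individual_ids=samples,
    )
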