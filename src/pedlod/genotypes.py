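"""Biallelic marker metadata, dosage matrices and PLINK/VCF round-trip I/O.

Dosages count copies of the minor allele (0/1/2), with ``-1`` for missing.
Individual ids are assumed unique across families (the simulator guarantees
this; the readers enforce it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .pedigree import Affection, Individual, Pedigree, PedigreeSet, PedigreeError, Sex


@dataclass
class MarkerInfo:
    marker_id: str
    chromosome: str = "1"
    position_bp: int = 1
    position_cm: float = 0.0
    major_allele: str = "A"
    minor_allele: str = "G"
    true_maf: float | None = None
    estimated_maf: float | None = None


class GenotypeMatrix:
    """Individuals x markers minor-allele dosage matrix."""

    MISSING = -1

    def __init__(
        self,
        samples: list[str],
        markers: list[MarkerInfo],
        dosages: np.ndarray,
    ):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(samples), len(markers)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids are not unique")
        self.samples = list(samples)
        self.markers = list(markers)
        self.dosages = dosages
        self._row = {s: k for k, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, sample: str) -> np.ndarray:
        """Dosages across markers for one individual."""
        return self.dosages[self._row[sample]]

    def __contains__(self, sample: str) -> bool:
        return sample in self._row

    def column(self, marker_index: int) -> np.ndarray:
        return self.dosages[:, marker_index]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples, [MarkerInfo(**vars(m)) for m in self.markers],
            self.dosages.copy(),
        )


# ---------------------------------------------------------------------------
# Mendelian consistency (biallelic dosage rules)
# ---------------------------------------------------------------------------

def _gamete_options(dosage: int) -> tuple[int, ...]:
    if dosage == 0:
        return (0,)
    if dosage == 1:
        return (0, 1)
    if dosage == 2:
        return (1,)
    return (0, 1)  # missing parent constrains nothing


def count_mendelian_errors(geno: GenotypeMatrix, peds: PedigreeSet) -> int:
    """Number of (trio, marker) combinations with an impossible dosage."""
    n_err = 0
    for p in peds:
        for ind in p.nonfounders():
            if ind.id not in geno:
                continue
            child = geno.row(ind.id)
            fa = geno.row(ind.father_id) if ind.father_id in geno else None
            mo = geno.row(ind.mother_id) if ind.mother_id in geno else None
            for j in range(geno.n_markers):
                c = int(child[j])
                if c < 0:
                    continue
                fo = _gamete_options(int(fa[j]) if fa is not None else -1)
                mo_opts = _gamete_options(int(mo[j]) if mo is not None else -1)
                if not any(c == a + b for a in fo for b in mo_opts):
                    n_err += 1
    return n_err


# ---------------------------------------------------------------------------
# PLINK .ped/.map
# ---------------------------------------------------------------------------

def write_plink(geno: GenotypeMatrix, peds: PedigreeSet, prefix) -> None:
    """Write a PLINK-compatible .ped/.map pair (allele codes, not dosages)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for m in geno.markers:
            fh.write(
                f"{m.chromosome}\t{m.marker_id}\t{m.position_cm:g}\t{m.position_bp}\n"
            )
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for p in peds:
            for ind in p:
                lead = (
                    f"{p.family_id} {ind.id} {ind.father_id or '0'} "
                    f"{ind.mother_id or '0'} {int(ind.sex)} "
                    f"{int(ind.affection) if ind.affection else 0}"
                )
                if ind.id in geno:
                    row = geno.row(ind.id)
                    parts = []
                    for j, m in enumerate(geno.markers):
                        d = row[j]
                        if d < 0:
                            parts.append("0 0")
                        elif d == 0:
                            parts.append(f"{m.major_allele} {m.major_allele}")
                        elif d == 1:
                            parts.append(f"{m.major_allele} {m.minor_allele}")
                        else:
                            parts.append(f"{m.minor_allele} {m.minor_allele}")
                    fh.write(lead + " " + " ".join(parts) + "\n")
                else:
                    fh.write(lead + " " + " ".join(["0 0"] * geno.n_markers) + "\n")


def read_plink(prefix) -> tuple[PedigreeSet, GenotypeMatrix]:
    """Read a .ped/.map pair written by :func:`write_plink`.

    Minor/major orientation is taken from the .map-order allele codes by
    frequency in the file (ties keep the first-seen allele as major).
    """
    prefix = Path(prefix)
    markers: list[MarkerInfo] = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            chrom, mid, cm, bp = line.split()
            markers.append(
                MarkerInfo(
                    marker_id=mid, chromosome=chrom,
                    position_cm=float(cm), position_bp=int(bp),
                )
            )
    n_mark = len(markers)
    peds: dict[str, Pedigree] = {}
    samples: list[str] = []
    raw_alleles: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_mark:
                raise PedigreeError(
                    f"{prefix}.ped:{lineno}: expected {6 + 2 * n_mark} "
                    f"columns, got {len(fields)}"
                )
            fam, iid, fa, mo, sex, aff = fields[:6]
            ind = Individual(
                id=iid, family_id=fam,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=Sex(int(sex)),
                affection=Affection(int(aff)) if aff in ("0", "1", "2") else Affection.UNKNOWN,
            )
            peds.setdefault(fam, Pedigree(fam)).add(ind)
            samples.append(iid)
            raw_alleles.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_mark)]
            )
    ped_set = PedigreeSet(peds.values())
    for p in ped_set:
        p.validate()
    dosages = np.full((len(samples), n_mark), GenotypeMatrix.MISSING, dtype=np.int8)
    for j, m in enumerate(markers):
        counts: dict[str, int] = {}
        for row in raw_alleles:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            continue
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        major = alleles[0]
        minor = alleles[1] if len(alleles) > 1 else m.minor_allele
        m.major_allele, m.minor_allele = major, minor
        for i, row in enumerate(raw_alleles):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            dosages[i, j] = (a1 == minor) + (a2 == minor)
    return ped_set, GenotypeMatrix(samples, markers, dosages)


# ---------------------------------------------------------------------------
# VCF (biallelic, GT only)
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path) -> None:
    gt_code = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    contigs = {m.chromosome for m in geno.markers}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pedlod\n")
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j, m in enumerate(geno.markers):
            col = geno.dosages[:, j]
            fh.write(
                f"{m.chromosome}\t{m.position_bp}\t{m.marker_id}\t"
                f"{m.major_allele}\t{m.minor_allele}\t.\t.\t.\tGT\t"
                + "\t".join(gt_code[int(d)] for d in col)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: list[MarkerInfo] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    lut = np.array([0, 1, GenotypeMatrix.MISSING, 2], dtype=np.int8)
    for v in vcf:
        markers.append(
            MarkerInfo(
                marker_id=v.ID or f"{v.CHROM}:{v.POS}",
                chromosome=str(v.CHROM),
                position_bp=int(v.POS),
                major_allele=v.REF,
                minor_allele=v.ALT[0] if v.ALT else ".",
            )
        )
        rows.append(lut[np.asarray(v.gt_types)])
    vcf.close()
    dosages = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, markers, dosages)
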