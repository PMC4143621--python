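"""Founders-only minor-allele frequency estimation with the monomorphic floor.

Only genotyped founders contribute to the estimate (standard practice for
pedigree data: founder genotypes are the independent draws from the
population).  Markers with no observed minor allele in founders — including
markers with no genotyped founder at all — receive the floor frequency
0.0001 so every marker can still be scored.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import PedigreeSet

MAF_FLOOR = 1e-4

logger = logging.getLogger(__name__)


def estimate_founder_maf(
    geno: GenotypeMatrix, peds: PedigreeSet
) -> pd.DataFrame:
    """Fill ``estimated_maf`` on every marker and return the frequency table.

    The estimate is minor-allele count over 2x the number of genotyped
    founders.  If the raw frequency exceeds 0.5, allele labels and dosages
    are flipped in place so the matrix keeps its minor-allele orientation.
    Returns a PLINK-style table: marker_id, n_founders_genotyped,
    minor_count, estimated_maf.
    """
    founder_ids = [i.id for p in peds for i in p.founders() if i.id in geno]
    if not founder_ids:
        raise ValueError("pedigree set contains no founders present in the matrix")
    rows = np.array([geno._row[i] for i in founder_ids])
    sub = geno.dosages[rows]            # (n_founders, n_markers)
    present = sub >= 0
    n_geno = present.sum(axis=0)
    minor = np.where(present, sub, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_geno > 0, minor / (2.0 * np.maximum(n_geno, 1)), 0.0)

    flipped = freq > 0.5
    if flipped.any():
        idx = np.nonzero(flipped)[0]
        for j in idx:
            m = geno.markers[j]
            m.major_allele, m.minor_allele = m.minor_allele, m.major_allele
            if m.true_maf is not None:
                # keep true_maf aligned with the (new) counted allele
                m.true_maf = 1.0 - m.true_maf
        cols = geno.dosages[:, idx]
        geno.dosages[:, idx] = np.where(cols >= 0, 2 - cols, cols)
        minor[idx] = 2 * n_geno[idx] - minor[idx]
        freq[idx] = 1.0 - freq[idx]

    floored = minor == 0
    freq[floored] = MAF_FLOOR
    n_floor = int(floored.sum())
    if n_floor:
        logger.info(
            "%d marker(s) with no minor allele in genotyped founders; "
            "MAF set to %g", n_floor, MAF_FLOOR,
        )
    for j, m in enumerate(geno.markers):
        m.estimated_maf = float(freq[j])
    return pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in geno.markers],
            "n_founders_genotyped": n_geno.astype(int),
            "minor_count": minor.astype(int),
            "estimated_maf": freq,
        }
    )


def write_freq_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
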