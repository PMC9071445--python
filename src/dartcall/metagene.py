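"""Metagene coordinates and the length-normalized region-enrichment test.

A site is mapped into the concatenated 5'UTR/CDS/3'UTR axis: each region is
rescaled to unit width, giving a metagene coordinate in [0,3) with the stop
codon at 2.0.  Region counts are compared to a length-normalized
expectation (proportional to the median region lengths of the gene category
under study) with a chi-square test on 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation import REGIONS, RegionModel

REGION_INDEX = {r: i for i, r in enumerate(REGIONS)}


@dataclass
class MetagenePosition:
    key: str
    region: str
    within_region_fraction: float
    metagene_coord: float


@dataclass
class RegionTestResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float


def assign_region(key: str, pos: int, model: RegionModel) -> MetagenePosition:
    """Place a genomic site on the metagene axis of its gene.

    Sites in the extended (unannotated) 3'UTR territory map into utr3 with
    the fraction computed over the extended length.
    """
    region, offset = model.locate(pos)
    length = model.region_lengths[region]
    if length <= 0:
        raise ValueError(f"{model.gene_id}: empty region {region}")
    frac = offset / length
    return MetagenePosition(key, region, frac, REGION_INDEX[region] + frac)


def region_enrichment_test(observed, median_lengths) -> RegionTestResult:
    """Chi-square test of site counts per region vs length-proportional
    expectation: expected_i = N * median_length_i / sum(median_lengths)."""
    obs = np.asarray(observed, dtype=float)
    ml = np.asarray(median_lengths, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("no observed sites")
    if np.any(ml <= 0):
        raise ValueError("median region lengths must be positive")
    expected = obs.sum() * ml / ml.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return RegionTestResult(obs, expected, float(chi2), len(obs) - 1, float(p))


def metagene_histogram(
    positions: list[MetagenePosition], n_bins_per_region: int = 10
) -> np.ndarray:
    """Counts over [0,3) with n_bins_per_region half-open bins per region."""
    coords = [p.metagene_coord for p in positions]
    hist, _ = np.histogram(coords, bins=3 * n_bins_per_region, range=(0.0, 3.0))
    return hist
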