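"""Per-sample abundance and Shannon-Wiener diversity indices.

For sample *j* with taxon proportions :math:`p_{ij}` over its :math:`S_j`
observed taxa, the Shannon-Wiener index (SWI) is

.. math:: H_j = -\\sum_{i=1}^{S_j} p_{ij} \\ln p_{ij}

reported in nats. To make samples comparable, the index is normalised by the
log of :math:`M`, the total number of distinct taxa observed across *all*
samples, giving :math:`H'_j = H_j / \\ln M \\in [0, 1]`. The ratio is
independent of the logarithm base. The abundance index of a sample is its
total number of taxonomically attributed reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .io_formats import TaxonomicProfile


@dataclass
class DiversityTable:
    """Per-sample indices plus the table-level taxon universe size M."""

    samples: pd.DataFrame  # columns: sample_id, abundance_index, richness, swi, normalized_swi
    m_total: int

    def to_frame(self) -> pd.DataFrame:
        df = self.samples.copy()
        df["m_total"] = self.m_total
        return df


def abundance_index(
    profile: TaxonomicProfile, count_unassigned: bool = False
) -> int:
    """Total reads attributed at the analysis rank (optionally incl. reads
    resolved only to higher nodes)."""
    total = sum(profile.counts.values())
    if count_unassigned:
        total += profile.unassigned_at_rank
    return total


def shannon_wiener(counts: Mapping[str, int] | Sequence[float]) -> float:
    """Shannon-Wiener index H = -sum p_i ln p_i, natural log.

    Raises on an empty profile: diversity of nothing is undefined.
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    if values.size == 0:
        raise ValueError("diversity is undefined for an empty profile")
    if np.any(values <= 0):
        raise ValueError("all counts must be strictly positive")
    # scipy normalises to proportions internally
    return float(entropy(values))


def normalized_swi(swi: float, m: int) -> float:
    """H' = H / ln M for a taxon universe of M >= 2 distinct taxa."""
    if m < 2:
        raise ValueError(f"normalisation requires M >= 2 distinct taxa, got {m}")
    if swi < 0:
        raise ValueError("SWI must be non-negative")
    return swi / np.log(m)


def diversity_table(
    profiles: Sequence[TaxonomicProfile], count_unassigned_in_abundance: bool = False
) -> DiversityTable:
    """Compute abundance, richness, SWI and normalised SWI for every sample.

    M is the number of distinct taxon names with positive count in the union
    of all profiles (observed universe, not database size).
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    ranks = {p.rank for p in profiles}
    if len(ranks) > 1:
        raise ValueError(f"profiles aggregated at mixed ranks: {sorted(ranks)}")
    universe: set[str] = set()
    for p in profiles:
        universe.update(t for t, c in p.counts.items() if c > 0)
    m = len(universe)
    if m < 2:
        raise ValueError(
            f"only {m} distinct taxa across all samples; normalisation needs >= 2"
        )
    rows = []
    for p in profiles:
        h = shannon_wiener(p.counts) if p.counts else float("nan")
        rows.append(
            {
                "sample_id": p.sample_id,
                "abundance_index": abundance_index(p, count_unassigned_in_abundance),
                "richness": len(p.counts),
                "swi": h,
                "normalized_swi": normalized_swi(h, m) if p.counts else float("nan"),
            }
        )
    return DiversityTable(samples=pd.DataFrame(rows), m_total=m)
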