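"""Compositional summaries and nonparametric group comparisons.

Domain and species proportion profiles per sample, and pairwise depth-layer
comparisons with the two-sided Wilcoxon rank-sum test, Bonferroni-adjusted
within each response variable (the three layer pairs form one family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_formats import LAYERS, SampleMetadata, TaxonomicProfile

logger = logging.getLogger(__name__)

DOMAINS = ("Archaea", "Bacteria", "Viruses")

# significance ladder used in figure annotations
_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class TestResult:
    group_a: str
    group_b: str
    statistic: float  # rank-sum W of group_a within the pooled ranking
    p_raw: float
    p_adjusted: float
    method: str  # "exact" | "normal"

    @property
    def stars(self) -> str:
        for threshold, stars in _STAR_THRESHOLDS:
            if self.p_adjusted <= threshold:
                return stars
        return "ns"


def domain_proportions(
    profiles: Sequence[TaxonomicProfile], metadata: Sequence[SampleMetadata]
) -> pd.DataFrame:
    """Per-sample proportions over {Archaea, Bacteria, Viruses}.

    Categories outside the three domains (e.g. Eukaryota) are dropped and the
    remainder renormalised. Samples with zero reads in the three domains are
    excluded. Profiles must be aggregated at superkingdom.
    """
    meta = {m.sample_id: m for m in metadata}
    rows = []
    for p in profiles:
        if p.rank != "superkingdom":
            raise ValueError(f"profile {p.sample_id} aggregated at {p.rank}, "
                             "expected superkingdom")
        if p.sample_id not in meta:
            raise ValueError(f"sample {p.sample_id} missing from metadata")
        in_set = {d: p.counts.get(d, 0) for d in DOMAINS}
        dropped = sum(c for t, c in p.counts.items() if t not in DOMAINS)
        total = sum(in_set.values())
        if dropped:
            logger.warning(
                "sample %s: dropping %d reads outside %s and renormalising",
                p.sample_id, dropped, DOMAINS,
            )
        if total == 0:
            logger.warning("sample %s: no reads in %s; excluded", p.sample_id, DOMAINS)
            continue
        m = meta[p.sample_id]
        row = {"sample_id": p.sample_id, "station": m.station,
               "layer": m.layer, "ocean": m.ocean}
        row.update({d: in_set[d] / total for d in DOMAINS})
        rows.append(row)
    return pd.DataFrame(rows)


def top_species(
    profiles: Sequence[TaxonomicProfile], n: int = 10
) -> tuple[list[str], pd.DataFrame]:
    """The n species with the highest total read count over all samples, and
    per-sample proportions over them plus an ``other`` bucket.

    Ties at rank n break by taxon-name lexicographic order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    totals: dict[str, int] = {}
    for p in profiles:
        for taxon, count in p.counts.items():
            totals[taxon] = totals.get(taxon, 0) + count
    ranked = sorted(totals, key=lambda t: (-totals[t], t))
    if len(ranked) < n:
        logger.warning("only %d species observed; returning all (requested %d)",
                       len(ranked), n)
    top = ranked[:n]
    rows = []
    for p in profiles:
        total = sum(p.counts.values())
        row: dict[str, object] = {"sample_id": p.sample_id}
        top_sum = 0.0
        for taxon in top:
            prop = p.counts.get(taxon, 0) / total if total else 0.0
            row[taxon] = prop
            top_sum += prop
        row["other"] = 1.0 - top_sum if total else 0.0
        rows.append(row)
    return top, pd.DataFrame(rows)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The exact null distribution is enumerated when ``mode='exact'`` or when
    ``mode='auto'`` with min(n1, n2) <= 10 and no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction is
    used. The returned statistic is the rank sum W of ``x`` in the pooled
    ranking. ``p_adjusted`` equals ``p_raw`` here; family-wise adjustment is
    applied by :func:`compare_layers`.
    """
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.all(pooled == pooled[0]):
        logger.warning("degenerate data: all values identical; p = 1")
        w = x.size * (pooled.size + 1) / 2.0
        return TestResult("x", "y", w, 1.0, 1.0, "degenerate")
    if mode == "exact" or (mode == "auto" and min(x.size, y.size) <= 10 and not has_ties):
        method = "exact"
    else:
        method = "normal"
    res = mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
    )
    # U -> rank-sum of x
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    p = float(min(res.pvalue, 1.0))
    return TestResult("x", "y", w, p, p, method)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p -> min(1, m p), order preserved.

    ``m`` defaults to the family size = len(p_values); it may be passed
    explicitly when the family is larger than the tests actually run.
    """
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-value {p} outside (0, 1]")
    return [min(1.0, m * p) for p in p_values]


def compare_layers(
    values: Mapping[str, float],
    metadata: Sequence[SampleMetadata],
    mode: str = "auto",
    group_by: str = "layer",
) -> list[TestResult]:
    """All pairwise group comparisons of a per-sample statistic.

    With the default ``group_by='layer'`` the three pairs SRF-DCM, SRF-MES
    and DCM-MES are tested; the Bonferroni family size is the number of
    comparisons actually performed (a pair is skipped with a warning when a
    group has fewer than 2 samples). ``group_by='ocean'`` or ``'station'``
    compares those groupings instead.
    """
    meta = {m.sample_id: m for m in metadata}
    by_group: dict[str, list[float]] = {}
    for sample_id, value in values.items():
        if sample_id not in meta:
            raise ValueError(f"sample {sample_id} missing from metadata")
        key = getattr(meta[sample_id], group_by)
        by_group.setdefault(key, []).append(float(value))
    if group_by == "layer":
        present = [g for g in LAYERS if g in by_group]
    else:
        present = sorted(by_group)
    if len(present) < 2:
        raise ValueError(f"need >= 2 groups with samples, found {present}")
    pairs = []
    for a, b in combinations(present, 2):
        if len(by_group[a]) < 2 or len(by_group[b]) < 2:
            logger.warning("pair %s-%s skipped: fewer than 2 samples in a group", a, b)
            continue
        pairs.append((a, b))
    results = []
    for a, b in pairs:
        r = wilcoxon_rank_sum(by_group[a], by_group[b], mode=mode)
        results.append(TestResult(a, b, r.statistic, r.p_raw, r.p_raw, r.method))
    family = len(results)
    adjusted = bonferroni([r.p_raw for r in results], m=family) if results else []
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
    return results


def test_results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.group_a, "group_b": r.group_b,
                "statistic": r.statistic, "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted, "method": r.method, "stars": r.stars,
            }
            for r in results
        ]
    )
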