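"""Per-depth-layer GO term frequencies, top-term matrices and exclusivity.

A term's frequency in a layer is its raw occurrence count: the total number
of annotation rows attached to reads of that layer's samples (a read with
two annotations contributes two occurrences). Counts are not normalised by
layer sequencing depth by default; an optional per-million normalisation is
available for display. A term is exclusive to a layer when its count there
is positive and exactly zero in both other layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import LAYERS, GOAnnotation, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class LayerTermFrequency:
    """term_id -> occurrence count per layer; absent means 0."""

    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {layer: {} for layer in LAYERS}
    )

    @property
    def universe(self) -> set[str]:
        terms: set[str] = set()
        for layer_counts in self.counts.values():
            terms.update(layer_counts)
        return terms

    def count(self, layer: str, term: str) -> int:
        return self.counts.get(layer, {}).get(term, 0)

    def layer_total(self, layer: str) -> int:
        return sum(self.counts.get(layer, {}).values())

    def to_frame(self) -> pd.DataFrame:
        terms = sorted(self.universe)
        return pd.DataFrame(
            {"term_id": terms,
             **{layer: [self.count(layer, t) for t in terms] for layer in LAYERS}}
        )


@dataclass
class ExclusivityReport:
    exclusive: dict[str, list[str]]  # layer -> sorted exclusive term ids

    def counts(self) -> dict[str, int]:
        return {layer: len(terms) for layer, terms in self.exclusive.items()}


def term_frequencies(
    annotations: Mapping[str, Sequence[GOAnnotation]],
    metadata: Sequence[SampleMetadata],
) -> LayerTermFrequency:
    """Pool annotation rows across all samples of each layer.

    ``annotations`` maps sample_id to that sample's annotation rows; every
    annotated sample must be present in the metadata.
    """
    meta = {m.sample_id: m for m in metadata}
    freq = LayerTermFrequency()
    for sample_id, rows in annotations.items():
        if sample_id not in meta:
            raise ValueError(f"annotations given for unknown sample {sample_id!r}")
        layer = meta[sample_id].layer
        layer_counts = freq.counts[layer]
        for ann in rows:
            layer_counts[ann.term_id] = layer_counts.get(ann.term_id, 0) + 1
    return freq


def top_terms_matrix(
    freq: LayerTermFrequency,
    n: int = 50,
    scope: str = "overall",
    normalize_per_million: bool = False,
) -> pd.DataFrame:
    """Matrix (terms x layers) of log10(count + 1) for the most common terms.

    ``scope='overall'`` selects the n terms with the largest summed count
    across layers; ``scope='per_layer'`` the union of each layer's top n.
    Rows are ordered by descending overall count, ties by term id. Raw counts
    are emitted alongside the log values.
    """
    if scope not in ("overall", "per_layer"):
        raise ValueError(f"unknown scope {scope!r}")
    if n <= 0:
        raise ValueError("n must be positive")
    universe = freq.universe
    if not universe:
        raise ValueError("empty term frequency table")
    overall = {t: sum(freq.count(layer, t) for layer in LAYERS) for t in universe}
    order = sorted(universe, key=lambda t: (-overall[t], t))
    if scope == "overall":
        if len(order) < n:
            logger.warning("only %d terms in the universe (requested %d)", len(order), n)
        selected = order[:n]
    else:
        chosen: set[str] = set()
        for layer in LAYERS:
            layer_order = sorted(
                (t for t in universe if freq.count(layer, t) > 0),
                key=lambda t: (-freq.count(layer, t), t),
            )
            chosen.update(layer_order[:n])
        selected = [t for t in order if t in chosen]
    totals = {layer: freq.layer_total(layer) for layer in LAYERS}
    rows = []
    for t in selected:
        row: dict[str, object] = {"term_id": t}
        for layer in LAYERS:
            c = freq.count(layer, t)
            row[f"count_{layer}"] = c
            value = c * 1e6 / totals[layer] if (normalize_per_million and totals[layer]) else c
            row[f"log10_{layer}"] = float(np.log10(value + 1))
        rows.append(row)
    return pd.DataFrame(rows)


def exclusive_terms(freq: LayerTermFrequency) -> ExclusivityReport:
    """Terms with positive count in exactly one layer, per layer, sorted."""
    for layer in LAYERS:
        if freq.layer_total(layer) == 0:
            logger.warning("layer %s has no annotations; treated as all-zero", layer)
    exclusive: dict[str, list[str]] = {layer: [] for layer in LAYERS}
    for term in sorted(freq.universe):
        positive = [layer for layer in LAYERS if freq.count(layer, term) > 0]
        if len(positive) == 1:
            exclusive[positive[0]].append(term)
    return ExclusivityReport(exclusive=exclusive)
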