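"""Synthetic multi-station, multi-layer community generator with ground truth.

Emulates the statistical structure of tropical/subtropical ocean shotgun
metagenomes sampled at three depth layers (SRF, DCM, MES): per-sample read
totals drawn log-uniformly over orders of magnitude, log-normal
species-abundance distributions within each domain, a per-layer domain mix in
which the archaeal share increases and the viral share decreases with depth,
a planted diversity ordering (the mesopelagic richer than the photic
layers), and per-layer exclusive GO terms on top of a shared functional
core. Classification tables, metadata and GO annotations are emitted in
exactly the dialects ``io_formats`` reads, alongside a JSON ground-truth
sidecar; identical seeds give byte-identical output directories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    LAYERS,
    ClassifiedRead,
    GOAnnotation,
    SampleMetadata,
    TaxonomicProfile,
    write_classification_table,
    write_table,
)

logger = logging.getLogger(__name__)

DOMAIN_ORDER = ("bacteria", "archaea", "viruses")
_DOMAIN_DISPLAY = {"bacteria": "Bacteria", "archaea": "Archaea", "viruses": "Viruses"}
_OCEANS = ("Indian", "South Atlantic", "South Pacific")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``domain_mix_by_layer`` triples are (bacteria, archaea, viruses)
    proportions of classified reads; ``richness_by_layer`` is the expected
    number of distinct species per sample, allocated across domains
    proportionally to the mix.
    """

    n_stations: int = 8
    samples_per_station_layer: dict[str, int] = field(
        default_factory=lambda: {"SRF": 3, "DCM": 3, "MES": 3}
    )
    species_pool_size: dict[str, int] = field(
        default_factory=lambda: {"bacteria": 300, "archaea": 80, "viruses": 150}
    )
    richness_by_layer: dict[str, int] = field(
        default_factory=lambda: {"SRF": 60, "DCM": 60, "MES": 150}
    )
    lognormal_sigma: float = 1.5
    domain_mix_by_layer: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "SRF": (0.71, 0.05, 0.24),
            "DCM": (0.745, 0.10, 0.155),
            "MES": (0.70, 0.25, 0.05),
        }
    )
    read_total_range: tuple[int, int] = (50_000, 40_000_000)
    unclassified_fraction: float = 0.10
    go_terms_shared: int = 300
    go_terms_exclusive_by_layer: dict[str, int] = field(
        default_factory=lambda: {"SRF": 24, "DCM": 53, "MES": 10}
    )
    go_terms_per_read_max: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_stations < 1:
            raise ValueError("n_stations must be positive")
        for layer in LAYERS:
            if self.samples_per_station_layer.get(layer, 0) < 1:
                raise ValueError(f"samples_per_station_layer[{layer}] must be positive")
            if self.richness_by_layer.get(layer, 0) < 1:
                raise ValueError(f"richness_by_layer[{layer}] must be positive")
            mix = self.domain_mix_by_layer[layer]
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"domain mix for {layer} sums to {sum(mix)}, not 1")
            if any(w < 0 for w in mix):
                raise ValueError(f"domain mix for {layer} has negative weights")
        for domain in DOMAIN_ORDER:
            if self.species_pool_size.get(domain, 0) < 1:
                raise ValueError(f"species_pool_size[{domain}] must be positive")
        lo, hi = self.read_total_range
        if not (0 < lo <= hi):
            raise ValueError("read_total_range must satisfy 0 < min <= max")
        if not (0 <= self.unclassified_fraction < 1):
            raise ValueError("unclassified_fraction must be in [0, 1)")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")
        if self.go_terms_shared < 1:
            raise ValueError("go_terms_shared must be positive")
        for layer in LAYERS:
            richness = self.richness_by_layer[layer]
            mix = self.domain_mix_by_layer[layer]
            for domain, w in zip(DOMAIN_ORDER, mix):
                if _domain_richness(richness, w) > self.species_pool_size[domain]:
                    raise ValueError(
                        f"layer {layer}: requested {domain} richness exceeds the "
                        f"pool of {self.species_pool_size[domain]} species"
                    )


def _domain_richness(total_richness: int, weight: float) -> int:
    return max(1, round(total_richness * weight)) if weight > 0 else 0


def default_config(seed: int = 0) -> GeneratorConfig:
    """The default study conditions (see class docstring)."""
    return GeneratorConfig(seed=seed)


@dataclass
class SampleTruth:
    sample_id: str
    station: str
    layer: str
    ocean: str
    read_total: int
    species: list[str]
    domain_mix: tuple[float, float, float]


@dataclass
class GroundTruth:
    samples: list[SampleTruth]
    shared_terms: list[str]
    exclusive_terms: dict[str, list[str]]  # layer -> term ids
    diversity_ordering: str = "MES > SRF = DCM"

    def to_json(self) -> str:
        payload = {
            "diversity_ordering": self.diversity_ordering,
            "shared_terms": self.shared_terms,
            "exclusive_terms": self.exclusive_terms,
            "samples": [
                {
                    "sample_id": s.sample_id, "station": s.station,
                    "layer": s.layer, "ocean": s.ocean,
                    "read_total": s.read_total, "species": s.species,
                    "domain_mix": list(s.domain_mix),
                }
                for s in self.samples
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class _Realisation:
    truth: SampleTruth
    species_counts: dict[str, int]  # species name -> reads (positive only)
    n_unclassified: int


def _species_pools(config: GeneratorConfig) -> dict[str, list[str]]:
    return {
        domain: [
            f"{_DOMAIN_DISPLAY[domain]} species {i:04d}"
            for i in range(1, config.species_pool_size[domain] + 1)
        ]
        for domain in DOMAIN_ORDER
    }


def _go_pools(config: GeneratorConfig) -> tuple[list[str], dict[str, list[str]]]:
    counter = 1
    shared = [f"GO:{i:07d}" for i in range(counter, counter + config.go_terms_shared)]
    counter += config.go_terms_shared
    exclusive: dict[str, list[str]] = {}
    for layer in LAYERS:
        n = config.go_terms_exclusive_by_layer.get(layer, 0)
        exclusive[layer] = [f"GO:{i:07d}" for i in range(counter, counter + n)]
        counter += n
    return shared, exclusive


def _realise_samples(config: GeneratorConfig) -> list[_Realisation]:
    config.validate()
    pools = _species_pools(config)
    realisations: list[_Realisation] = []
    sample_index = 0
    log_lo, log_hi = np.log(config.read_total_range[0]), np.log(config.read_total_range[1])
    for station_no in range(1, config.n_stations + 1):
        station = f"{station_no:03d}"
        ocean = _OCEANS[(station_no - 1) % len(_OCEANS)]
        for layer in LAYERS:
            mix = config.domain_mix_by_layer[layer]
            richness = config.richness_by_layer[layer]
            for rep in range(1, config.samples_per_station_layer[layer] + 1):
                rng = np.random.default_rng([config.seed, sample_index, 0])
                sample_id = f"T{station}-{layer}-R{rep}"
                read_total = int(round(np.exp(rng.uniform(log_lo, log_hi))))
                read_total = max(read_total, config.read_total_range[0])
                species: list[str] = []
                proportions: list[np.ndarray] = []
                for domain, weight in zip(DOMAIN_ORDER, mix):
                    s_d = _domain_richness(richness, weight)
                    if s_d == 0:
                        continue
                    chosen = rng.choice(len(pools[domain]), size=s_d, replace=False)
                    species.extend(pools[domain][i] for i in sorted(chosen))
                    abund = np.exp(rng.normal(0.0, config.lognormal_sigma, size=s_d))
                    proportions.append(weight * abund / abund.sum())
                p = np.concatenate(proportions)
                p = p / p.sum()
                counts = rng.multinomial(read_total, p)
                species_counts = {
                    sp: int(c) for sp, c in zip(species, counts) if c > 0
                }
                f = config.unclassified_fraction
                n_unclassified = int(round(read_total * f / (1.0 - f))) if f else 0
                truth = SampleTruth(sample_id, station, layer, ocean,
                                    read_total, species, mix)
                realisations.append(_Realisation(truth, species_counts, n_unclassified))
                sample_index += 1
    return realisations


def _lineage_for(species: str) -> tuple[str | None, ...]:
    domain = species.split(" ")[0]
    genus = f"{domain} genus {species.rsplit(' ', 1)[-1][:2]}"
    return (domain, f"{domain} phylum", f"{domain} class", f"{domain} order",
            f"{domain} family", genus, species)


def simulate_profiles(
    config: GeneratorConfig,
) -> tuple[list[TaxonomicProfile], list[SampleMetadata], GroundTruth]:
    """In-memory counterpart of :func:`generate_dataset`.

    Returns species-rank profiles whose counts equal the per-species row
    tallies the file path would emit, without materialising per-read rows.
    """
    realisations = _realise_samples(config)
    shared, exclusive = _go_pools(config)
    profiles = [
        TaxonomicProfile(sample_id=r.truth.sample_id, rank="species",
                         counts=dict(r.species_counts), unassigned_at_rank=0)
        for r in realisations
    ]
    metadata = [
        SampleMetadata(r.truth.sample_id, r.truth.station, r.truth.layer, r.truth.ocean)
        for r in realisations
    ]
    truth = GroundTruth(samples=[r.truth for r in realisations],
                        shared_terms=shared, exclusive_terms=exclusive)
    return profiles, metadata, truth


def domain_profile(profile: TaxonomicProfile) -> TaxonomicProfile:
    """Collapse a generator species-rank profile to superkingdom."""
    counts: dict[str, int] = {}
    for species, c in profile.counts.items():
        domain = species.split(" ")[0]
        counts[domain] = counts.get(domain, 0) + c
    return TaxonomicProfile(sample_id=profile.sample_id, rank="superkingdom",
                            counts=counts,
                            unassigned_at_rank=profile.unassigned_at_rank)


def _annotation_rows(
    realisation: _Realisation,
    sample_index: int,
    config: GeneratorConfig,
    layer_terms: list[str],
    ensure_coverage: bool,
) -> list[GOAnnotation]:
    """Random 0..max terms per classified read from the layer's term set;
    for the coverage sample every term of the set is guaranteed one row."""
    rng = np.random.default_rng([config.seed, sample_index, 1])
    n_reads = sum(realisation.species_counts.values())
    rows: list[GOAnnotation] = []
    k_per_read = rng.integers(0, config.go_terms_per_read_max + 1, size=n_reads)
    total_terms = int(k_per_read.sum())
    term_idx = rng.integers(0, len(layer_terms), size=total_terms)
    cursor = 0
    for read_no in range(n_reads):
        read_id = f"{realisation.truth.sample_id}_r{read_no + 1:07d}"
        for _ in range(int(k_per_read[read_no])):
            rows.append(GOAnnotation(read_id, layer_terms[term_idx[cursor]]))
            cursor += 1
    if ensure_coverage:
        seen = {r.term_id for r in rows}
        missing = [t for t in layer_terms if t not in seen]
        for i, term in enumerate(missing):
            read_id = f"{realisation.truth.sample_id}_r{(i % max(n_reads, 1)) + 1:07d}"
            rows.append(GOAnnotation(read_id, term))
    return rows


def simulate_annotations(
    config: GeneratorConfig, truth: GroundTruth
) -> dict[str, list[GOAnnotation]]:
    """Per-sample GO annotation rows matching the realised read counts."""
    realisations = _realise_samples(config)
    shared, exclusive = _go_pools(config)
    first_of_layer: set[str] = set()
    annotations: dict[str, list[GOAnnotation]] = {}
    for idx, r in enumerate(realisations):
        layer = r.truth.layer
        layer_terms = shared + exclusive[layer]
        cover = layer not in first_of_layer
        first_of_layer.add(layer)
        annotations[r.truth.sample_id] = _annotation_rows(
            r, idx, config, layer_terms, ensure_coverage=cover
        )
    return annotations


def _classification_rows(realisation: _Realisation):
    read_no = 0
    # classified rows grouped by species, in the sample's species order
    for species, count in realisation.species_counts.items():
        lineage = _lineage_for(species)
        for _ in range(count):
            read_no += 1
            yield ClassifiedRead(True, f"{realisation.truth.sample_id}_r{read_no:07d}",
                                 1000 + hash_taxid(species), lineage)
    for _ in range(realisation.n_unclassified):
        read_no += 1
        yield ClassifiedRead(False, f"{realisation.truth.sample_id}_r{read_no:07d}", 0)


def hash_taxid(species: str) -> int:
    # stable small pseudo-taxid derived from the name (not a real NCBI id)
    return sum(ord(c) * (i + 1) for i, c in enumerate(species)) % 100_000


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> GroundTruth:
    """Write a complete synthetic dataset and return its ground truth.

    Layout: ``metadata.tsv``, ``classifications/<sample>.tsv`` (Kaiju
    dialect), ``annotations/<sample>.tsv`` (read_id, GO term) and
    ``ground_truth.json``. Identical config (incl. seed) gives byte-identical
    directories.
    """
    out = Path(out_dir)
    (out / "classifications").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    profiles, metadata, truth = simulate_profiles(config)
    annotations = simulate_annotations(config, truth)
    realisations = _realise_samples(config)
    write_table(
        [
            {"sample_id": m.sample_id, "station": m.station,
             "layer": m.layer, "ocean": m.ocean}
            for m in metadata
        ],
        out / "metadata.tsv",
    )
    for r in realisations:
        write_classification_table(
            _classification_rows(r), out / "classifications" / f"{r.truth.sample_id}.tsv"
        )
        with (out / "annotations" / f"{r.truth.sample_id}.tsv").open(
            "w", encoding="utf-8"
        ) as fh:
            for ann in annotations[r.truth.sample_id]:
                fh.write(f"{ann.read_id}\t{ann.term_id}\n")
    (out / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
    logger.info("synthetic dataset with %d samples written to %s", len(metadata), out)
    return truth


def scaled_config(config: GeneratorConfig, read_total: int) -> GeneratorConfig:
    """The same study conditions at a fixed reduced read depth (for fast
    simulation studies and tests)."""
    return replace(config, read_total_range=(read_total, read_total))
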