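"""End-to-end orchestration: profiles -> diversity -> clustering -> layer
comparisons -> functional profiling, driven by one validated configuration.

Products (all TSV except the Newick tree): diversity.tsv, groups.tsv,
tree.nwk, domain_proportions.tsv, tests.tsv, terms.tsv, exclusive.tsv, plus
a manifest.json recording the config hash, package version and per-stage row
counts. Outputs are deterministic: identical config and inputs give
byte-identical products.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import DEFAULT_MOJENA_K, euclidean_distances, mojena_cut, to_newick, upgma
from .diversity import diversity_table
from .functional import exclusive_terms, term_frequencies, top_terms_matrix
from .io_formats import (
    aggregate_profile,
    read_go_annotations,
    read_kaiju_table,
    read_metadata,
    write_table,
)
from .stats import compare_layers, domain_proportions, test_results_frame

logger = logging.getLogger(__name__)

PRODUCTS = ("diversity.tsv", "groups.tsv", "tree.nwk", "domain_proportions.tsv",
            "tests.tsv", "terms.tsv", "exclusive.tsv")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    classifications_dir: str
    metadata: str
    out_dir: str
    annotations_dir: str | None = None
    rank: str = "species"
    mojena_k: float = DEFAULT_MOJENA_K
    cluster_features: str = "normalized_swi"  # or "taxon_profile"
    top_species_n: int = 10
    top_terms_n: int = 50
    top_terms_scope: str = "overall"
    seed: int = 0

    _KNOWN = (
        "classifications_dir", "metadata", "out_dir", "annotations_dir", "rank",
        "mojena_k", "cluster_features", "top_species_n", "top_terms_n",
        "top_terms_scope", "seed",
    )

    def validate(self) -> None:
        if not Path(self.classifications_dir).is_dir():
            raise PipelineError(
                f"stage validate_config: classifications dir not found: "
                f"{self.classifications_dir}"
            )
        if not Path(self.metadata).is_file():
            raise PipelineError(
                f"stage validate_config: metadata file not found: {self.metadata}"
            )
        if self.annotations_dir is not None and not Path(self.annotations_dir).is_dir():
            raise PipelineError(
                f"stage validate_config: annotations dir not found: "
                f"{self.annotations_dir}"
            )
        if self.mojena_k <= 0:
            raise PipelineError("stage validate_config: mojena_k must be positive")
        if self.top_species_n <= 0 or self.top_terms_n <= 0:
            raise PipelineError("stage validate_config: top-N parameters must be positive")
        if self.cluster_features not in ("normalized_swi", "taxon_profile"):
            raise PipelineError(
                f"stage validate_config: unknown cluster_features "
                f"{self.cluster_features!r}"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config, reject unknown keys, fill defaults, validate."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise PipelineError("stage validate_config: config must be a mapping")
    unknown = set(raw) - set(PipelineConfig._KNOWN)
    if unknown:
        raise PipelineError(
            f"stage validate_config: unknown config keys {sorted(unknown)}"
        )
    raw.update(overrides)
    missing = {k for k in ("classifications_dir", "metadata", "out_dir") if k not in raw}
    if missing:
        raise PipelineError(f"stage validate_config: missing required keys {sorted(missing)}")
    config = PipelineConfig(**raw)
    config.validate()
    logger.info("effective config: %s", asdict(config))
    return config


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name}: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "products": {},
        "complete": False,
    }

    def record(name: str, n_rows: int) -> None:
        manifest["products"][name] = {"rows": n_rows}

    try:
        metadata = _stage("read_metadata")(read_metadata, config.metadata)
        cls_dir = Path(config.classifications_dir)

        def load_profiles():
            species, domains = [], []
            for m in metadata:
                path = cls_dir / f"{m.sample_id}.tsv"
                if not path.is_file():
                    raise FileNotFoundError(f"no classification table for {m.sample_id}")
                reads = read_kaiju_table(path)
                species.append(aggregate_profile(reads, config.rank, m.sample_id))
                domains.append(aggregate_profile(reads, "superkingdom", m.sample_id))
            return species, domains

        species_profiles, domain_profiles = _stage("profiles")(load_profiles)

        div = _stage("diversity")(diversity_table, species_profiles)
        write_table(div.to_frame(), out / "diversity.tsv")
        record("diversity.tsv", len(div.samples))

        def cluster():
            if config.cluster_features == "normalized_swi":
                features = {
                    row.sample_id: [row.normalized_swi]
                    for row in div.samples.itertuples()
                }
            else:
                taxa = sorted({t for p in species_profiles for t in p.counts})
                features = {}
                for p in species_profiles:
                    total = sum(p.counts.values())
                    features[p.sample_id] = [
                        p.counts.get(t, 0) / total if total else 0.0 for t in taxa
                    ]
            dm = euclidean_distances(features)
            dendro = upgma(dm)
            result, assignment = mojena_cut(dendro, k=config.mojena_k)
            return dendro, result, assignment

        dendro, mojena, assignment = _stage("clustering")(cluster)
        groups_df = pd.DataFrame(
            [
                {"sample_id": s, "group": g, "n_groups": mojena.n_groups,
                 "theta": mojena.theta, "alpha_mean": mojena.alpha_mean,
                 "alpha_sd": mojena.alpha_sd}
                for s, g in assignment.groups.items()
            ]
        )
        write_table(groups_df, out / "groups.tsv")
        record("groups.tsv", len(groups_df))
        newick = to_newick(dendro)
        (out / "tree.nwk").write_text(newick + "\n", encoding="utf-8")
        record("tree.nwk", 1)

        props = _stage("domain_proportions")(domain_proportions, domain_profiles, metadata)
        write_table(props, out / "domain_proportions.tsv")
        record("domain_proportions.tsv", len(props))

        def comparisons():
            frames = []
            responses = {
                "normalized_swi": dict(zip(div.samples.sample_id, div.samples.normalized_swi)),
                "abundance_index": dict(zip(div.samples.sample_id, div.samples.abundance_index)),
            }
            for domain in ("Archaea", "Bacteria", "Viruses"):
                responses[f"proportion_{domain}"] = dict(zip(props.sample_id, props[domain]))
            for response, values in responses.items():
                results = compare_layers(values, metadata)
                frame = test_results_frame(results)
                frame.insert(0, "response", response)
                frames.append(frame)
            return pd.concat(frames, ignore_index=True)

        tests_df = _stage("compare_layers")(comparisons)
        write_table(tests_df, out / "tests.tsv")
        record("tests.tsv", len(tests_df))

        def functional():
            if config.annotations_dir is None:
                return None, None
            ann_dir = Path(config.annotations_dir)
            annotations = {}
            for m in metadata:
                path = ann_dir / f"{m.sample_id}.tsv"
                if path.is_file():
                    annotations[m.sample_id] = read_go_annotations(path)
            freq = term_frequencies(annotations, metadata)
            terms = top_terms_matrix(freq, n=config.top_terms_n,
                                     scope=config.top_terms_scope)
            report = exclusive_terms(freq)
            return terms, report

        terms_df, report = _stage("functional")(functional)
        if terms_df is not None:
            write_table(terms_df, out / "terms.tsv")
            record("terms.tsv", len(terms_df))
            excl_df = pd.DataFrame(
                [
                    {"layer": layer, "term_id": term}
                    for layer in ("SRF", "DCM", "MES")
                    for term in report.exclusive[layer]
                ]
            )
            write_table(excl_df, out / "exclusive.tsv", allow_empty=True)
            record("exclusive.tsv", len(excl_df))
        manifest["complete"] = True
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    return manifest
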