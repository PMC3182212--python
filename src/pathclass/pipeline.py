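"""End-to-end pipeline: load/generate -> filter -> features -> rank -> IFS.

A run is driven by a flat configuration mapping (YAML on disk) and leaves a
manifest recording the config snapshot, input hashes, seeds and per-block
feature counts — enough to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .feature_table import FeatureTable, build_table, write_table
from .io import filter_benchmark, load_dataset, read_annotations
from .model import PathwayClassModel
from .synthetic import SyntheticSpec, generate

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class RunManifest:
    config: dict
    input_hashes: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    counts: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a flat mapping")
    return cfg


def run_all(config: dict, outdir) -> RunManifest:
    """Execute the full pipeline described by ``config``.

    Config keys (flat):

    * either ``synthetic: true`` plus any :class:`SyntheticSpec` field, or
      the input paths ``pathways`` (list), ``fasta``, ``annotations``,
      ``labels``;
    * ``seed`` (also the synthetic seed), ``depth`` (ranking/IFS depth),
      ``min_proteins``, ``background_size``, ``neighbor_degree``,
      ``t4_denominator``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config), seed=config.get("seed"))
    t0 = time.perf_counter()

    stage = "load"
    try:
        if config.get("synthetic"):
            spec_fields = {
                k: v
                for k, v in config.items()
                if k in SyntheticSpec.__dataclass_fields__
            }
            spec_fields.setdefault("seed", config.get("seed", 0))
            if "proteins_per_pathway" in spec_fields:
                spec_fields["proteins_per_pathway"] = tuple(
                    spec_fields["proteins_per_pathway"]
                )
            if "sequence_length" in spec_fields:
                spec_fields["sequence_length"] = tuple(spec_fields["sequence_length"])
            ds = generate(SyntheticSpec(**spec_fields))
            pathways, proteins, universe = ds.pathways, ds.proteins, ds.universe
        else:
            for key in ("pathways", "fasta", "annotations", "labels"):
                if key not in config:
                    raise ConfigError(f"missing required config key {key!r}")
            for f in list(config["pathways"]) + [
                config["fasta"], config["annotations"], config["labels"]
            ]:
                if not Path(f).exists():
                    raise ConfigError(f"input file not found: {f}")
                manifest.input_hashes[str(f)] = _sha256(f)
            pathways, proteins, universe = load_dataset(
                config["pathways"],
                config["fasta"],
                config["annotations"],
                config["labels"],
                background_size=config.get("background_size"),
            )
        manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "filter"
        t = time.perf_counter()
        pathways = filter_benchmark(
            pathways, proteins, min_proteins=int(config.get("min_proteins", 3))
        )
        if not pathways:
            raise DataError("no pathways survive benchmark filtering")
        manifest.counts["pathways"] = len(pathways)
        manifest.counts["universe_terms"] = len(universe)
        manifest.timings_s[stage] = time.perf_counter() - t

        stage = "features"
        t = time.perf_counter()
        table = build_table(
            pathways,
            proteins,
            universe,
            neighbor_degree=config.get("neighbor_degree", "total"),
            t4_denominator=config.get("t4_denominator", "out"),
        )
        for b in ("graph", "physchem", "functional"):
            manifest.counts[f"{b}_features"] = table.block_size(b)
        manifest.counts["total_features"] = table.n_features
        table_path = outdir / "feature_table.tsv"
        write_table(table, table_path)
        manifest.outputs.append(str(table_path))
        manifest.timings_s[stage] = time.perf_counter() - t

        stage = "rank"
        t = time.perf_counter()
        depth = int(config.get("depth", 50))
        model = PathwayClassModel.from_feature_table(table)
        ranking = model.rank_features(depth=depth)
        for which in ("maxrel", "mrmr"):
            p = outdir / f"{which}_list.tsv"
            ranking.write_tsv(p, which=which)
            manifest.outputs.append(str(p))
        manifest.timings_s[stage] = time.perf_counter() - t

        stage = "ifs"
        t = time.perf_counter()
        results = model.fit(depth=depth, ranking=ranking)
        curve_path = outdir / "ifs_curve.tsv"
        results.sweep.write_tsv(curve_path)
        report_path = outdir / "predictions.tsv"
        results.jackknife_report().to_csv(report_path, sep="\t", index=False)
        manifest.outputs.extend([str(curve_path), str(report_path)])
        manifest.counts["best_n_features"] = results.best_n_features
        manifest.timings_s[stage] = time.perf_counter() - t
        manifest.counts["best_accuracy_pct"] = round(results.best_accuracy * 100, 4)
        with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(results.summary() + "\n")
        manifest.outputs.append(str(outdir / "summary.txt"))
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise DataError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest.write(outdir / "manifest.json")
    return manifest
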