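"""End-to-end orchestration: expression -> partition -> motif enrichment.

Every run writes a manifest (parameters, seed, input checksums, package
version) sufficient to re-execute it exactly; outputs carry the seed in a
header comment and are byte-identical across reruns with the same inputs
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

from . import __version__
from .accessibility import directory_provider, uniform_provider
from .compartment import (
    rank_and_partition,
    read_expression,
    retention_table,
    write_partition,
)
from .enrichment import results_frame, scan_collection
from .gene_models import RegionKind, read_transcripts, select_longest_isoform
from .motif import read_motif_collection

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    fasta: str
    annotation: str
    expression: str
    sample_metadata: str
    motifs: str
    out_dir: str
    seed: int
    region: str = "three_prime_utr"
    baseline_timepoint: str = "0h"
    lps_timepoint: str | None = None  # default: latest timepoint in metadata
    positive_size: int = 70
    fc_threshold: float = 2.0
    negative_threshold: float = 1.1
    epsilon: float = 1.0
    accessibility: str = "uniform"  # "uniform" or "dir:<path>"
    folds: int = 5
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path, **overrides):
        """Flat key = value config file; CLI overrides win."""
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        kv.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("seed", "positive_size", "folds"):
            if key in kv:
                kv[key] = int(kv[key])
        for key in ("fc_threshold", "negative_threshold", "epsilon"):
            if key in kv:
                kv[key] = float(kv[key])
        return cls(**kv)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_with_header(df, path, seed, **to_csv_kwargs):
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n", **to_csv_kwargs)


def track_provider_from_spec(spec: str):
    if spec == "uniform":
        return uniform_provider
    if spec.startswith("dir:"):
        return directory_provider(spec[4:])
    raise ValueError(f"unknown accessibility provider {spec!r} (use uniform or dir:<path>)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict.

    Output files: retention.tsv, partition.tsv, positive_ids.txt,
    negative_ids.txt, enrichment.tsv, manifest.json under ``out_dir``.
    Partial outputs are removed if any stage fails.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    out = {
        name: os.path.join(config.out_dir, fname)
        for name, fname in (
            ("retention", "retention.tsv"),
            ("partition", "partition.tsv"),
            ("positive_ids", "positive_ids.txt"),
            ("negative_ids", "negative_ids.txt"),
            ("enrichment", "enrichment.tsv"),
            ("manifest", "manifest.json"),
        )
    }
    written: list[str] = []
    t0 = time.perf_counter()
    try:
        stage = "gene_models"
        try:
            records = select_longest_isoform(
                read_transcripts(config.fasta, config.annotation)
            )
            by_id = {r.transcript_id: r for r in records}
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        logger.info("stage %s: %d transcripts (%.2fs)", stage, len(records),
                    time.perf_counter() - t0)

        stage = "compartment_analysis"
        try:
            matrix = read_expression(config.expression, config.sample_metadata)
            lps_tp = config.lps_timepoint
            if lps_tp is None:
                lps_tp = [t for t in matrix.timepoints()
                          if t != config.baseline_timepoint][-1]
            table = retention_table(
                matrix, config.baseline_timepoint, lps_tp,
                fc_threshold=config.fc_threshold, epsilon=config.epsilon,
            )
            partition = rank_and_partition(
                table, positive_size=config.positive_size,
                negative_threshold=config.negative_threshold,
            )
            _write_with_header(table, out["retention"], config.seed,
                               float_format="%.6g")
            write_partition(partition, out["partition"], out["positive_ids"],
                            out["negative_ids"])
            written += [out["retention"], out["partition"],
                        out["positive_ids"], out["negative_ids"]]
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        logger.info("stage %s: %d positive / %d negative", stage,
                    len(partition.positive_ids), len(partition.negative_ids))

        stage = "motif_enrichment"
        try:
            motifs = read_motif_collection(config.motifs)
            provider = track_provider_from_spec(config.accessibility)
            results = scan_collection(
                motifs, partition, by_id, RegionKind(config.region),
                provider, folds=config.folds, seed=config.seed,
            )
            _write_with_header(results_frame(results), out["enrichment"],
                               config.seed, index=False, float_format="%.6g")
            written.append(out["enrichment"])
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        logger.info("stage %s: %d motifs tested (%.2fs total)", stage,
                    len(results), time.perf_counter() - t0)

        manifest = {
            "package": "retscan",
            "version": __version__,
            "seed": config.seed,
            "parameters": {k: v for k, v in asdict(config).items() if k != "extra"},
            "lps_timepoint_used": lps_tp,
            "inputs": {
                name: {"path": path, "sha256": _sha256(path)}
                for name, path in (
                    ("fasta", config.fasta),
                    ("annotation", config.annotation),
                    ("expression", config.expression),
                    ("sample_metadata", config.sample_metadata),
                    ("motifs", config.motifs),
                )
            },
            "outputs": {k: v for k, v in out.items() if k != "manifest"},
        }
        with open(out["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(out["manifest"])
        return manifest
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise


def rerun_from_manifest(manifest_path: str, out_dir: str) -> dict:
    """Re-execute a run from its manifest (round-trip reproducibility)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    params = dict(manifest["parameters"])
    params["out_dir"] = out_dir
    params.pop("extra", None)
    return run_pipeline(PipelineConfig(**params))
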