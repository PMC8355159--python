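"""Reproducible end-to-end runs: ingest -> clones -> metrics -> overlap.

A run writes every stage output as TSV/JSON into one directory together
with a manifest of SHA-256 content hashes and a log of the parameters,
seed, and library versions that produced it.  Re-running with identical
config and inputs reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .airr_io import (
    GermlineSet,
    SequenceRecord,
    filter_functional,
    read_airr_tsv,
    read_germline_fasta,
    write_airr_tsv,
    write_germline_fasta,
    write_skip_report,
)
from .clones import CloneSet, call_clones
from .metrics import (
    cdr3_length_distribution,
    d20_table,
    replicate_jaccard_table,
    shm_table,
    vh_usage_matrix,
)
from .overlap import compute_overlap
from .simulate import SimConfig, simulate, write_truth_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass(slots=True)
class RunConfig:
    """Parameters of a pipeline run; defaults are the published analysis'."""

    out_dir: str | Path = "ighrep_run"
    #: AIRR rearrangement TSV; None means simulate instead
    input_tsv: str | Path | None = None
    germline_v_fasta: str | Path | None = None
    germline_j_fasta: str | Path | None = None
    simulate: bool = False
    seed: int = 0
    identity_threshold: float = 0.85
    collapse_max_nt_dist: int = 2
    mutated_threshold_percent: float = 1.0
    top_n_vh: int = 20
    functional_only: bool = True
    min_overlap_subsets: int = 2
    column_map: dict = field(default_factory=dict)
    #: generator parameters for simulate=True; None uses the default
    #: study design with this run's seed
    sim_config: SimConfig | None = None


def _jsonable(obj):
    """Recursively coerce config values (paths, frozenset keys) for JSON."""
    if isinstance(obj, dict):
        return {
            ("&".join(sorted(k)) if isinstance(k, frozenset) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kwargs)
        written.append(path)

    stage = "ingest"
    try:
        records, germlines = _load_inputs(config, out, written)
        if config.functional_only:
            before = len(records)
            records = filter_functional(records)
            logger.info("functional filter: %d -> %d records", before, len(records))

        stage = "clone_inference"
        clone_set = call_clones(
            records,
            threshold=config.identity_threshold,
            max_nt_dist=config.collapse_max_nt_dist,
        )
        save_df(clone_set.clone_table(), "clones.tsv", index=False)
        save_df(clone_set.assignments(), "assignments.tsv", index=False)

        stage = "metrics"
        save_df(d20_table(clone_set), "d20.tsv", index=False)
        save_df(replicate_jaccard_table(clone_set), "replicate_jaccard.tsv", index=False)
        if germlines is not None:
            save_df(
                shm_table(clone_set, germlines, mutated_threshold_percent=config.mutated_threshold_percent),
                "shm.tsv",
                index=False,
            )
        lengths = [
            {"strain": strain, "subset": subset, "cdr3_len_nt": int(n)}
            for strain, subset in clone_set.strata()
            for n in cdr3_length_distribution(clone_set, strain, subset)
        ]
        save_df(pd.DataFrame(lengths), "cdr3_lengths.tsv", index=False)
        usage = vh_usage_matrix(clone_set, top_n=config.top_n_vh)
        save_df(usage.raw, "vh_usage_raw.tsv")
        save_df(usage.normalized, "vh_usage_normalized.tsv")

        stage = "overlap"
        for mouse_id in sorted(clone_set.mouse_strains):
            res = compute_overlap(clone_set, mouse_id, min_subsets=config.min_overlap_subsets)
            save_df(res.jaccard, f"overlap_jaccard_{mouse_id}.tsv")
            save_df(res.cosine, f"overlap_cosine_{mouse_id}.tsv")
            venn_path = out / f"overlap_venn_{mouse_id}.json"
            venn_path.write_text(json.dumps(res.venn_counts, indent=2, sort_keys=True))
            written.append(venn_path)
            from .overlap import presence_tracks

            tracks, counts = presence_tracks(res.presence, min_subsets=config.min_overlap_subsets)
            long = tracks.reset_index(names="clone_id").melt(
                id_vars="clone_id", var_name="subset", value_name="copies"
            )
            save_df(long, f"overlap_tracks_{mouse_id}.tsv", index=False)
    except Exception:
        manifest = {"status": "failed", "failed_stage": stage, "files": {}}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.exception("pipeline failed in stage %s", stage)
        raise

    log = {
        "ighrep_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "parameters": _jsonable(asdict(config)),
        "n_records": len(records),
        "n_clones": len(clone_set),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    written.append(log_path)

    manifest = {
        "status": "ok",
        "files": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _load_inputs(
    config: RunConfig, out: Path, written: list[Path]
) -> tuple[list[SequenceRecord], GermlineSet | None]:
    if config.simulate:
        sim_cfg = config.sim_config or SimConfig(seed=config.seed)
        records, truth, germlines = simulate(sim_cfg)
        write_airr_tsv(records, out / "simulated_rearrangements.tsv")
        write_germline_fasta(germlines, out / "germline_v.fasta", out / "germline_j.fasta")
        write_truth_tsv(truth, out / "simulated_truth.tsv")
        written.extend(
            out / n
            for n in (
                "simulated_rearrangements.tsv",
                "germline_v.fasta",
                "germline_j.fasta",
                "simulated_truth.tsv",
            )
        )
        return records, germlines
    if config.input_tsv is None:
        raise ValueError("RunConfig needs input_tsv or simulate=True")
    skipped: list[dict] = []
    records = read_airr_tsv(config.input_tsv, column_map=config.column_map or None, skipped=skipped)
    if skipped:
        write_skip_report(skipped, out / "ingest_skipped.tsv")
        written.append(out / "ingest_skipped.tsv")
    germlines = None
    if config.germline_v_fasta and config.germline_j_fasta:
        germlines = read_germline_fasta(config.germline_v_fasta, config.germline_j_fasta)
    return records, germlines
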