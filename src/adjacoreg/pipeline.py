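"""End-to-end orchestration: config in, machine-readable reports out.

Every report embeds a provenance block (input checksums, parameters,
seed, package version) so any number can be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .adjacency import run_adjacency_analysis
from .annotation import read_annotation
from .concordance import concordance_matrix, read_gene_lists
from .de import read_de_table

__all__ = ["RunConfig", "run_full_pipeline"]

log = logging.getLogger("adjacoreg")


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    annotation: str
    de_table: str
    annotation_format: str = "tsv"
    families: Optional[str] = None  # TSV: gene_id, family_id
    reference_lists: Optional[str] = None  # TSV for concordance stage
    min_abs_log2fc: float = 0.8
    max_p: float = 0.05
    control_size: Optional[int] = None  # None -> match deregulated set size
    n_perm: int = 0
    seed: int = 0
    out_dir: str = "adjacoreg_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(config: RunConfig) -> dict:
    inputs = {"annotation": config.annotation, "de_table": config.de_table}
    if config.families:
        inputs["families"] = config.families
    if config.reference_lists:
        inputs["reference_lists"] = config.reference_lists
    for stage_name, p in inputs.items():
        if not Path(p).exists():
            raise RuntimeError(f"[{stage_name} stage] input file not found: {p}")
    return {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_abs_log2fc": config.min_abs_log2fc,
            "max_p": config.max_p,
            "control_size": config.control_size,
            "n_perm": config.n_perm,
        },
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
    }


def _jsonable(value):
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, float) and math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return value


def read_family_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "family_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: family TSV missing columns {sorted(missing)}")
    return dict(zip(df["gene_id"], df["family_id"]))


def run_full_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; write reports under ``config.out_dir``.

    Returns ``{"adjacency": <path>, "concordance": <path or None>}``.
    Any stage failure raises with a stage-named message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = _provenance(config)

    def stage(name: str):
        log.info("stage=%s parameters=%s", name, provenance["parameters"])

    try:
        stage("annotation")
        catalogue = read_annotation(config.annotation, config.annotation_format)
    except Exception as exc:
        raise RuntimeError(f"[annotation stage] {exc}") from exc
    try:
        stage("de_table")
        de = read_de_table(config.de_table)
    except Exception as exc:
        raise RuntimeError(f"[de_table stage] {exc}") from exc

    family_map = None
    if config.families:
        try:
            family_map = read_family_map(config.families)
        except Exception as exc:
            raise RuntimeError(f"[families stage] {exc}") from exc
    if family_map is None:
        family_map = catalogue.family_map()

    try:
        stage("adjacency")
        report = run_adjacency_analysis(
            catalogue,
            de,
            min_abs_log2fc=config.min_abs_log2fc,
            max_p=config.max_p,
            family_map=family_map,
            control_size=config.control_size,
            n_perm=config.n_perm,
            seed=config.seed,
        )
    except Exception as exc:
        raise RuntimeError(f"[adjacency stage] {exc}") from exc

    adjacency_path = out_dir / "adjacency_report.json"
    payload = {
        "provenance": provenance,
        "adjacency": {k: _jsonable(v) for k, v in report.to_dict().items()},
    }
    adjacency_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    concordance_path = None
    if config.reference_lists:
        try:
            stage("concordance")
            lists = read_gene_lists(config.reference_lists)
            matrix = concordance_matrix(lists, de, max_p=config.max_p)
        except Exception as exc:
            raise RuntimeError(f"[concordance stage] {exc}") from exc
        concordance_path = out_dir / "concordance.tsv"
        matrix.to_csv(concordance_path, sep="\t", index=False)

    return {
        "adjacency": str(adjacency_path),
        "concordance": str(concordance_path) if concordance_path else None,
    }
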