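"""End-to-end run orchestration from a single declarative JSON config.

A run wires the stages together: (optionally) build a signature from a
labeled reference, deconvolve the mixture matrix, aggregate fractions into
coarse groups, and run the configured group contrasts. Every effective
parameter is echoed into a manifest JSON so a run can be reproduced exactly
from its manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregation import GroupingScheme, aggregate_fractions
from .deconvolution import deconvolve
from .io import (
    read_expression_table,
    read_metadata,
    read_signature_table,
    validate_metadata,
    write_signature_table,
)
from .signature import ReferenceDataset, build_signature
from .stats import paired_compare, unpaired_compare

logger = logging.getLogger(__name__)


@dataclass
class ContrastSpec:
    test: str  # "paired" | "unpaired"
    key: str
    a: str
    b: str
    pair_key: str = "subject_id"
    bh: bool = True


@dataclass
class RunConfig:
    mixtures: str
    metadata: str
    out_dir: str
    scale: str = "log2"
    signature: str | None = None
    reference: str | None = None
    reference_labels: str | None = None
    solver: str = "svr"
    g_min: int = 50
    g_max: int = 150
    q_threshold: float = 0.3
    grouping_scheme: str | None = None
    contrasts: list[ContrastSpec] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        contrasts = [ContrastSpec(**c) for c in raw.pop("contrasts", [])]
        return cls(contrasts=contrasts, **raw)

    def validate(self) -> None:
        for label, p in [("mixtures", self.mixtures), ("metadata", self.metadata)]:
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.signature is None and self.reference is None:
            raise ValueError("config needs either a signature or a reference to build one")
        for label, p in [
            ("signature", self.signature),
            ("reference", self.reference),
            ("reference_labels", self.reference_labels),
            ("grouping_scheme", self.grouping_scheme),
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest.

    A stage failure marks the stage failed in the manifest, skips downstream
    stages, and re-raises for a non-zero process exit.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {**asdict(config)},
        "stages": {},
        "outputs": [],
    }

    def _finish(stage: str, status: str, err: Exception | None = None):
        manifest["stages"][stage] = status
        if err is not None:
            manifest["stages"][stage] = f"failed: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        if config.signature:
            signature = read_signature_table(config.signature)
        else:
            expr = read_expression_table(config.reference, "log2")
            labels = pd.read_csv(config.reference_labels, sep="\t", dtype=str)
            label_map = dict(zip(labels.iloc[:, 0], labels.iloc[:, 1]))
            ref = ReferenceDataset(expr, label_map)
            signature = build_signature(
                ref, g_min=config.g_min, g_max=config.g_max, q_threshold=config.q_threshold
            )
            write_signature_table(signature, out / "signature.tsv")
            (out / "signature_provenance.json").write_text(
                json.dumps(
                    {"G": signature.G, "condition_number": signature.condition_number,
                     **signature.provenance},
                    indent=2,
                )
            )
            manifest["outputs"] += ["signature.tsv", "signature_provenance.json"]
        _finish("signature", "ok")
    except Exception as exc:  # noqa: BLE001 - manifest must record any failure
        _finish("signature", "failed", exc)
        raise

    try:
        mixtures = read_expression_table(config.mixtures, config.scale)
        metadata = read_metadata(config.metadata)
        validate_metadata(metadata, mixtures)
        result = deconvolve(mixtures, signature, solver=config.solver)
        result.fractions.to_csv(out / "fractions.tsv", sep="\t", float_format="%.12g",
                                index_label="sample_id")
        result.fit_stats.to_csv(out / "fit_stats.tsv", sep="\t", float_format="%.12g",
                                index_label="sample_id")
        manifest["outputs"] += ["fractions.tsv", "fit_stats.tsv"]
        _finish("deconvolve", "ok")
    except Exception as exc:  # noqa: BLE001
        _finish("deconvolve", "failed", exc)
        raise

    try:
        if config.grouping_scheme:
            scheme = GroupingScheme.from_tsv(config.grouping_scheme)
            grouped = aggregate_fractions(result.fractions, scheme)
            grouped.to_csv(out / "fractions_grouped.tsv", sep="\t", float_format="%.12g",
                           index_label="sample_id")
            manifest["outputs"].append("fractions_grouped.tsv")
        _finish("aggregate", "ok")
    except Exception as exc:  # noqa: BLE001
        _finish("aggregate", "failed", exc)
        raise

    try:
        tables = []
        for c in config.contrasts:
            if c.test == "paired":
                t = paired_compare(result.fractions, metadata, c.key, c.a, c.b,
                                   pair_key=c.pair_key, bh=c.bh)
            elif c.test == "unpaired":
                t = unpaired_compare(result.fractions, metadata, c.key, c.a, c.b, bh=c.bh)
            else:
                raise ValueError(f"unknown contrast test {c.test!r}")
            tables.append(t)
        if tables:
            stats = pd.concat(tables, ignore_index=True)
            stats["significant_unadjusted"] = stats["p_value"] < 0.05
            if "q_value" in stats:
                stats["significant_bh"] = stats["q_value"] < 0.05
            stats.to_csv(out / "contrasts.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["outputs"].append("contrasts.tsv")
        _finish("statistics", "ok")
    except Exception as exc:  # noqa: BLE001
        _finish("statistics", "failed", exc)
        raise

    return manifest
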