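"""End-to-end orchestration: QC → signature scores → noise → abundance.

All stages run on the same retained-nucleus set produced by QC. A single
global seed fans out deterministically to stage-specific seeds via a stable
hash of the stage name, so rerunning with an identical configuration yields
a byte-identical report body (timestamps live outside the hashed body).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import abundance_analysis
from .datatypes import ConfigError, GeneSet
from .io import read_cohort, read_gene_set, read_gmt, write_tsv
from .noise import NoiseParams, transcriptional_noise
from .qc import QCThresholds, run_qc
from .signatures import ScoreParams, diversity_score, normalize_log1p, pathway_scores, select_hvgs_per_type

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    qc: QCThresholds = field(default_factory=QCThresholds)
    noise: NoiseParams = field(default_factory=NoiseParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    ltsr_threshold: float = 0.9
    gene_set_files: dict = field(default_factory=dict)  # name -> path (list or GMT)
    hvg_reference_condition: str = "LP"
    n_hvg: int = 200
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = dict(raw)
        if "qc" in kwargs:
            kwargs["qc"] = QCThresholds(**kwargs["qc"])
        if "noise" in kwargs:
            kwargs["noise"] = NoiseParams(**kwargs["noise"])
        if "score" in kwargs:
            kwargs["score"] = ScoreParams(**kwargs["score"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"invalid pipeline configuration: {exc}") from exc

    def validate(self) -> None:
        if not Path(self.input_dir).exists():
            raise ConfigError(f"input directory {self.input_dir} does not exist")
        for name, p in self.gene_set_files.items():
            if not Path(p).exists():
                raise ConfigError(f"gene set file for {name!r} not found: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        body = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(body.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    qc_summary: dict
    noise: dict
    abundance: dict
    score_summary: dict
    provenance: dict

    def body(self) -> dict:
        return {
            "qc_summary": self.qc_summary,
            "noise": self.noise,
            "abundance": self.abundance,
            "score_summary": self.score_summary,
            "provenance": {k: v for k, v in self.provenance.items() if k != "timestamp"},
        }

    def to_json(self) -> str:
        out = self.body()
        out["provenance"] = dict(self.provenance)
        return json.dumps(out, indent=2, sort_keys=True, allow_nan=False, default=_jsonify)

    def report_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.body(), sort_keys=True, allow_nan=False, default=_jsonify).encode()
        ).hexdigest()

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        raw = json.loads(text)
        return cls(
            qc_summary=raw["qc_summary"],
            noise=raw["noise"],
            abundance=raw["abundance"],
            score_summary=raw["score_summary"],
            provenance=raw["provenance"],
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _finite(x: float):
    """JSON-safe float: infinities become signed sentinels, NaN becomes None."""
    x = float(x)
    if np.isnan(x):
        return None
    if np.isinf(x):
        return "+inf" if x > 0 else "-inf"
    return x


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run the full analysis on a cohort directory and write its outputs.

    A stage failure aborts with the stage name; a ``STALE`` marker naming
    the failed stage is left in the output directory so partial outputs are
    recognizable, and is removed on success.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stale = out_dir / "STALE"

    def _enter(stage: str):
        stale.write_text(f"incomplete run: failed or interrupted at stage {stage!r}\n")

    _enter("read")
    matrix, table = read_cohort(config.input_dir)

    # -- QC ------------------------------------------------------------
    _enter("qc")
    fmatrix, ftable, qc_report, qc_summary = run_qc(matrix, table, config.qc)
    write_tsv(out_dir / "qc_report.tsv", qc_report)

    # -- signature scores ----------------------------------------------
    _enter("score")
    score_params = dataclasses.replace(config.score, seed=stage_seed(config.seed, "score"))
    norm = normalize_log1p(fmatrix, config.score.normalization_scale)
    gene_sets = {}
    for name, path in sorted(config.gene_set_files.items()):
        if str(path).endswith(".gmt"):
            gene_sets.update(read_gmt(path))
        else:
            gene_sets[name] = read_gene_set(path, name)
    score_summary: dict = {"sets": {}, "diversity": {}}
    scores_frames = []
    if gene_sets:
        pscores = pathway_scores(norm, ftable, gene_sets, score_params)
        scores_frames.append(pscores)
        grouped = pscores.groupby(["set", "cell_type", "condition"])["score"].mean()
        score_summary["sets"] = {
            f"{s}|{t}|{c}": _finite(v) for (s, t, c), v in grouped.items()
        }
    hvg_sets = select_hvgs_per_type(
        norm, ftable, condition=config.hvg_reference_condition, n_hvg=config.n_hvg
    )
    if hvg_sets:
        div = diversity_score(norm, ftable, hvg_sets, score_params)
        div_out = div.rename(columns={"score": "score"}).assign(set="diversity")[
            ["cell_id", "set", "score", "condition", "cell_type"]
        ]
        scores_frames.append(div_out)
        grouped = div.dropna(subset=["score"]).groupby(["cell_type", "condition"])["score"].mean()
        score_summary["diversity"] = {f"{t}|{c}": _finite(v) for (t, c), v in grouped.items()}
    if scores_frames:
        all_scores = pd.concat(scores_frames, ignore_index=True)
        all_scores = all_scores.sort_values(["set", "cell_type", "condition", "cell_id"])
        write_tsv(out_dir / "scores.tsv", all_scores)

    # -- transcriptional noise -----------------------------------------
    _enter("noise")
    noise_params = dataclasses.replace(config.noise, seed=stage_seed(config.seed, "noise"))
    noise_res = transcriptional_noise(fmatrix, ftable, noise_params)
    write_tsv(out_dir / "noise_by_type.tsv", noise_res.per_group)
    write_tsv(out_dir / "noise_ratio.tsv", noise_res.ratios)
    noise_dict = {
        "per_group": [
            {k: (_finite(v) if isinstance(v, float) else v) for k, v in row.items()}
            for row in noise_res.per_group.to_dict("records")
        ],
        "log2_ratios": {
            r["cell_type"]: _finite(r["log2_ratio"]) for r in noise_res.ratios.to_dict("records")
        },
        "skipped_types": list(noise_res.skipped_types),
        "library_target": int(noise_res.library_target),
    }

    # -- abundance ------------------------------------------------------
    _enter("abundance")
    abundance = abundance_analysis(ftable, threshold=config.ltsr_threshold)
    abundance_out = abundance.reset_index().rename(
        columns={"n_baseline": "n_LP", "n_treatment": "n_HP"}
    )
    write_tsv(out_dir / "abundance.tsv", abundance_out)
    abundance_dict = {
        row["cell_type"]: {
            "log2fc": _finite(row["log2fc"]),
            "se": _finite(row["se"]),
            "ltsr": _finite(row["ltsr"]),
            "called": bool(row["called"]),
        }
        for row in abundance_out.to_dict("records")
    }

    report = AnalysisReport(
        qc_summary=qc_summary,
        noise=noise_dict,
        abundance=abundance_dict,
        score_summary=score_summary,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    (out_dir / "report.json").write_text(report.to_json(), encoding="utf-8")
    stale.unlink(missing_ok=True)
    return report
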