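"""File formats and end-to-end pipeline orchestration.

All tabular artifacts are UTF-8, comma-separated CSV with RFC-4180
quoting and "." decimals; resource tables and lexica are TSV.  The
pipeline runs the stages in order — generate/ingest, code, trim,
norm, analyse — emitting a report per stage, and never loses rows
silently: every input row is accounted for as accepted, rejected or
removed at a named stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as an
from . import coding as cd
from . import norming as nm
from . import rt as rtmod
from . import simulate as sim

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "PipelineResult",
    "read_trials",
    "write_trials",
    "write_norms",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

REQUIRED_TRIAL_COLUMNS = [
    "participant_id",
    "list_id",
    "image_id",
    "object_id",
    "raw_response",
    "rt_ms",
]

#: The eight Table-2 style natural-vs-artefact contrast variables.
CONTRAST_VARIABLES = [
    "agreement_pct",
    "h_normalised",
    "mean_rt_ms",
    "modal_production_frequency",
    "modal_zipf",
    "weighted_zipf",
    "modal_length_letters",
    "weighted_length_letters",
]


class SchemaError(ValueError):
    """Raised when an input file lacks required columns."""


# ---------------------------------------------------------------------------
# Trial-level CSV
# ---------------------------------------------------------------------------

def read_trials(path, rejects_path=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read trial-level naming data, routing malformed rows to a rejects table.

    Rows with a non-numeric or non-positive ``rt_ms``, or with an empty
    participant/image identifier, are collected (with a ``reject_reason``
    column) rather than silently dropped, and written to ``rejects_path``
    when given.  Raises :class:`SchemaError` naming any missing columns.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trials file {path} lacks required columns: {missing}")

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[rt.isna()] = "non-numeric rt_ms"
    reasons[rt.notna() & (rt <= 0)] = "non-positive rt_ms"
    for col in ("participant_id", "image_id"):
        blank = df[col].str.strip() == ""
        reasons[blank & (reasons == "")] = f"empty {col}"

    bad = reasons != ""
    rejects = df[bad].assign(reject_reason=reasons[bad])
    accepted = df[~bad].copy()
    accepted["rt_ms"] = rt[~bad].astype(float)
    if "trial_index" in accepted.columns:
        accepted["trial_index"] = pd.to_numeric(
            accepted["trial_index"], errors="coerce"
        )
    if len(rejects):
        logger.warning("%d malformed trial row(s) routed to rejects", len(rejects))
        if rejects_path is not None:
            rejects.to_csv(rejects_path, index=False)
    return accepted.reset_index(drop=True), rejects.reset_index(drop=True)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial-level table as UTF-8 RFC-4180 CSV."""
    trials.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def _round_floats(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out


def write_norms(norms: pd.DataFrame, path, decimals: int = 2) -> None:
    """Serialise the norms table, rounding floats only at this boundary."""
    _round_floats(norms, decimals).to_csv(
        path, index=False, encoding="utf-8", lineterminator="\n"
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(float(obj)) or math.isinf(float(obj)) else float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    In ``synthetic`` mode the generator produces trials, lexicon and
    coding resources from ``seed``; in ``real-data`` mode the three
    input paths are required.
    """

    mode: str = "synthetic"
    seed: int = 0
    out_dir: str = "norms_output"
    trials_path: str | None = None
    lexicon_path: str | None = None
    bigram_lexicon_path: str | None = None
    resources_dir: str | None = None
    corpus_tokens: int = 201_000_000
    long_ms: float = 10_000.0
    short_ms: float = 200.0
    sd_criterion: float = 2.5
    family_alpha: float = 0.05
    n_tests: int | None = None
    # synthetic-mode knobs (generator defaults when None)
    design: dict = field(default_factory=dict)
    rt_model: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    concentration: float = 0.16
    n_candidates: int = 8
    image_concentration: float = 150.0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real-data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.long_ms <= 0 or self.short_ms <= 0 or self.sd_criterion <= 0:
            raise ValueError("trimming thresholds must be positive")
        if self.mode == "real-data":
            for name in ("trials_path", "lexicon_path", "resources_dir"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"real-data mode requires existing {name}, got {p!r}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory results plus the paths of everything written."""

    norms: pd.DataFrame
    summary: pd.DataFrame
    coding_report: cd.CodingReport
    trim_report: rtmod.TrimReport
    flagged_participants: list
    analysis: dict
    out_dir: Path
    n_trials_in: int
    n_rejected: int


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _analyse(norms: pd.DataFrame, family_alpha: float, n_tests: int | None) -> dict:
    """Run the full inferential battery over a norms table."""
    result: dict = {}
    h_fit = an.fit_linear(norms, "mean_rt_ms", ["h_bits"])
    result["rt_on_h"] = h_fit.as_dict()

    comparison = an.hierarchical_comparison(norms)
    result["model_comparison"] = comparison.as_dict()
    modal_fit = comparison.fits["modal_step2"]
    weighted_fit = comparison.fits["weighted_step2"]
    result["suppression"] = {
        "modal": an.suppression_check(
            norms, "mean_rt_ms", "modal_zipf", "modal_length_letters", modal_fit
        ).as_dict(),
        "weighted": an.suppression_check(
            norms,
            "mean_rt_ms",
            "weighted_zipf",
            "weighted_length_letters",
            weighted_fit,
        ).as_dict(),
    }
    contrasts = an.welch_contrasts(
        norms, CONTRAST_VARIABLES, family_alpha=family_alpha, n_tests=n_tests
    )
    result["contrasts"] = [c.as_dict() for c in contrasts]
    result["within_object"] = an.within_object_consistency(norms).as_dict()
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole norming pipeline and write every artifact.

    Stages: generate or ingest trials; code responses; trim RTs and
    screen participants; compile per-image norms; run the analyses.
    Outputs under ``config.out_dir``: trials.csv (synthetic mode),
    rejects.csv, coded.csv, retained_rts.csv, norms.csv, summary.csv,
    coding_report.json, trim_report.json, analysis.json, config.yaml.
    Outputs contain no timestamps, so a fixed seed and config give
    byte-identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: mode=%s seed=%d config=%s",
                config.mode, config.seed, config.config_hash())

    rejects = pd.DataFrame()
    if config.mode == "synthetic":
        study = sim.simulate_study(
            design=sim.StudyDesign(**config.design) if config.design else None,
            rt_model=sim.RTModel(**config.rt_model) if config.rt_model else None,
            noise=sim.NoiseConfig(**config.noise) if config.noise else None,
            seed=config.seed,
            concentration=config.concentration,
            n_candidates=config.n_candidates,
            image_concentration=config.image_concentration,
        )
        trials, resources, lexicon = study.trials, study.resources, study.lexicon
        write_trials(trials, out / "trials.csv")
        resources.to_dir(out / "resources")
        lexicon.to_tsv(out / "lexicon.tsv", out / "bigram_lexicon.tsv")
    else:
        trials, rejects = read_trials(config.trials_path, out / "rejects.csv")
        resources = cd.CodingResources.from_dir(config.resources_dir)
        lexicon = nm.Lexicon.from_tsv(
            config.lexicon_path,
            config.corpus_tokens,
            config.bigram_lexicon_path,
        )
    n_in = len(trials) + len(rejects)

    coded = cd.code_trials(trials, resources)
    report = cd.coding_report(coded)
    coded.to_csv(out / "coded.csv", index=False, encoding="utf-8", lineterminator="\n")
    write_json(report.as_dict(), out / "coding_report.json")

    retained, trim_report = rtmod.trim_rts(
        coded,
        long_ms=config.long_ms,
        short_ms=config.short_ms,
        sd_criterion=config.sd_criterion,
    )
    retained, flagged = rtmod.participant_screen(
        retained, sd_criterion=config.sd_criterion
    )
    retained.to_csv(
        out / "retained_rts.csv", index=False, encoding="utf-8", lineterminator="\n"
    )
    trim_payload = trim_report.as_dict()
    trim_payload["participants_flagged"] = list(flagged)
    write_json(trim_payload, out / "trim_report.json")

    rt_means = rtmod.image_mean_rt(retained)
    norms, summary = nm.compile_image_norms(coded, lexicon, rt_means)
    write_norms(norms, out / "norms.csv")
    _round_floats(summary.reset_index()).to_csv(
        out / "summary.csv", index=False, encoding="utf-8", lineterminator="\n"
    )

    analysis_payload = _analyse(norms, config.family_alpha, config.n_tests)
    analysis_payload["seed"] = config.seed
    analysis_payload["config_hash"] = config.config_hash()
    analysis_payload["accounting"] = {
        "n_trials_in": n_in,
        "n_rejected": len(rejects),
        "n_coded": len(coded),
        "rt_trim": trim_report.as_dict(),
    }
    write_json(analysis_payload, out / "analysis.json")
    config.to_yaml(out / "config.yaml")

    return PipelineResult(
        norms=norms,
        summary=summary,
        coding_report=report,
        trim_report=trim_report,
        flagged_participants=list(flagged),
        analysis=analysis_payload,
        out_dir=out,
        n_trials_in=n_in,
        n_rejected=len(rejects),
    )
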