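"""End-to-end runs: discovery (select a signature and evaluate it) and
validation (apply a frozen signature to a new cohort).

Discovery and validation are deliberately separated, mirroring the use
of independent patient cohorts: validation never re-runs selection and
never mutates the signature file.  Reports are plain dicts (JSON-ready)
that embed the package version and a hash of the configuration that
produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .cohort import Platform, load_annotation
from .datasets import HOUSEKEEPING_PRIMER_PANEL, SORAFENIB_TARGETS
from .errors import ConfigError, SorasigError
from .evaluation import equal_error_threshold, roc_auc
from .normalization import load_expression_matrix, normalize
from .signature import (
    default_epsilon,
    differential_expression,
    load_signature,
    save_signature,
    score_samples,
    select_signature,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery", "run_validation"]


@dataclass
class RunConfig:
    """Validated configuration for a discovery or validation run."""

    platform: str
    matrix: str
    annotation: str
    signature: str | None = None        # input signature (validation only)
    candidates: tuple[str, ...] = SORAFENIB_TARGETS
    housekeeping: tuple[str, ...] = HOUSEKEEPING_PRIMER_PANEL
    epsilon: float | None = None        # None = platform default
    threshold_policy: str = "rates"
    fc_scale: str = "linear"
    equal_var: bool = True
    seed: int = 0

    def validate(self, require_signature: bool = False) -> None:
        try:
            Platform(self.platform)
        except ValueError:
            raise ConfigError(f"unknown platform {self.platform!r}") from None
        for name in ("matrix", "annotation"):
            path = getattr(self, name)
            if path is None:
                raise ConfigError(f"config is missing the {name} path")
            if not Path(path).is_file():
                raise ConfigError(f"{name} file not found: {path}")
        if require_signature:
            if self.signature is None:
                raise ConfigError("validation requires a signature file")
            if not Path(self.signature).is_file():
                raise ConfigError(f"signature file not found: {self.signature}")
        if self.threshold_policy not in ("rates", "counts"):
            raise ConfigError(f"unknown threshold policy {self.threshold_policy!r}")
        if self.fc_scale not in ("linear", "log"):
            raise ConfigError(f"unknown fold-change scale {self.fc_scale!r}")
        if not self.candidates:
            raise ConfigError("candidate gene list is empty")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise pipeline errors with the
    failing stage attached."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SorasigError):
                exc.args = (f"[{name}] {exc.args[0]}",) + exc.args[1:]
            if exc is None:
                logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _load_inputs(config: RunConfig):
    platform = Platform(config.platform)
    with _stage("load"):
        matrix = load_expression_matrix(config.matrix, platform)
        annotation = load_annotation(config.annotation, platform=platform)
    with _stage("normalize"):
        normalized = normalize(matrix, housekeeping=config.housekeeping)
    return platform, normalized, annotation


def _report_skeleton(config: RunConfig, stage: str) -> dict:
    return {
        "package": "sorasig",
        "version": __version__,
        "stage": stage,
        "platform": config.platform,
        "config_hash": config.hash(),
    }


def run_discovery(config: RunConfig, signature_out: str | Path | None = None) -> dict:
    """normalize -> differential expression -> selection -> score -> evaluate.

    Returns a JSON-ready report; optionally serializes the selected
    signature to ``signature_out`` for later validation runs.
    """
    config.validate()
    platform, normalized, annotation = _load_inputs(config)
    with _stage("differential_expression"):
        de = differential_expression(
            normalized, annotation, config.candidates,
            equal_var=config.equal_var, fc_scale=config.fc_scale,
        )
    with _stage("select_signature"):
        signature = select_signature(de, config.candidates)
    epsilon = config.epsilon
    if epsilon is None and platform is not Platform.PCR_CT:
        epsilon = default_epsilon(platform)
    with _stage("score"):
        scores = score_samples(normalized, signature, epsilon=epsilon)
    with _stage("evaluate"):
        roc = roc_auc(scores, annotation)
        threshold = equal_error_threshold(scores, annotation, policy=config.threshold_policy)
    if signature_out is not None:
        save_signature(signature, signature_out, platform=platform, epsilon=scores.epsilon)
        logger.info("signature written to %s", signature_out)
    report = _report_skeleton(config, "discovery")
    report.update(
        {
            "differential_expression": de.reset_index().to_dict(orient="records"),
            "signature": {
                "genes": list(signature.genes),
                "verdicts": {g: v.value for g, v in signature.verdicts.items()},
                "epsilon": scores.epsilon,
            },
            "scores": {s: float(v) for s, v in scores.scores.items()},
            "auc": roc.auc,
            "threshold_report": threshold.as_dict(),
        }
    )
    return report


def run_validation(config: RunConfig) -> dict:
    """Apply a frozen signature (no reselection) to a new cohort and
    evaluate it.  The signature file is read, never written."""
    config.validate(require_signature=True)
    with _stage("load_signature"):
        signature, meta = load_signature(config.signature)
    platform, normalized, annotation = _load_inputs(config)
    epsilon = config.epsilon
    if epsilon is None:
        epsilon = meta.get("epsilon")
    with _stage("score"):
        scores = score_samples(normalized, signature, epsilon=epsilon)
    with _stage("evaluate"):
        roc = roc_auc(scores, annotation)
        threshold = equal_error_threshold(scores, annotation, policy=config.threshold_policy)
    report = _report_skeleton(config, "validation")
    report.update(
        {
            "signature": {"genes": list(signature.genes), "file": str(config.signature)},
            "scores": {s: float(v) for s, v in scores.scores.items()},
            "auc": roc.auc,
            "threshold_report": threshold.as_dict(),
        }
    )
    return report
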