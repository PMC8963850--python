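"""Drug-target signature: screening, selection, scoring.

The signature is built from a fixed candidate list (the drug's known
molecular targets) by a deliberately simple rule: keep every candidate
whose normalized expression is higher in responders than in poor
responders (log2 fold-change > 0).  The per-sample score is then the
unweighted sum of log10-transformed normalized expression over the
selected genes (for qPCR, the sum of ΔCt values, which are already on
a log2 scale).  Higher score = predicted responder.

The simplicity is the point: with cohorts of 12-22 samples, weighted or
regression-based signatures overfit, while a directionality-filtered sum
reduces dimensionality without fitting any coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import CohortAnnotation, Platform
from .errors import DataError, DegenerateDataError
from .normalization import DeltaCtTable, ExpressionMatrix

__all__ = [
    "TargetGeneSet",
    "Verdict",
    "SignatureDefinition",
    "ScoreSet",
    "differential_expression",
    "select_signature",
    "score_samples",
    "default_epsilon",
    "save_signature",
    "load_signature",
]


@dataclass(frozen=True)
class TargetGeneSet:
    """Candidate drug-target genes (HGNC symbols, unique, non-empty)."""

    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataError("target gene set must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("target gene set contains duplicates")


class Verdict(str, Enum):
    INCLUDED = "included"
    EXCLUDED_DOWNREGULATED = "excluded_downregulated"
    EXCLUDED_MISSING = "excluded_missing"


@dataclass
class SignatureDefinition:
    """Outcome of the selection rule: final gene list plus per-candidate verdict."""

    candidates: tuple[str, ...]
    verdicts: dict[str, Verdict]
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not set(self.genes) <= set(self.candidates):
            raise DataError("signature genes must be a subset of the candidates")


@dataclass
class ScoreSet:
    """Per-sample signature score with the provenance needed to reproduce it."""

    scores: pd.Series  # index = sample ids
    platform: Platform
    signature_genes: tuple[str, ...]
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise DataError("non-finite signature score")


def _group_values(
    data: pd.DataFrame, annotation: CohortAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    common = [s for s in data.columns if s in set(annotation.sample_ids)]
    if not common:
        raise DataError("no overlap between matrix samples and annotation")
    is_resp = annotation.is_responder
    resp = [s for s in common if is_resp[s]]
    poor = [s for s in common if not is_resp[s]]
    if len(resp) < 2 or len(poor) < 2:
        raise DegenerateDataError(
            f"each response group needs >=2 samples (got {len(resp)} responders, {len(poor)} poor)"
        )
    return data[resp], data[poor]


def differential_expression(
    matrix: Union[ExpressionMatrix, DeltaCtTable],
    annotation: CohortAnnotation,
    genes: TargetGeneSet | Iterable[str],
    equal_var: bool = True,
    fc_scale: str = "linear",
) -> pd.DataFrame:
    """Two-group differential expression of the candidate genes.

    Per gene: two-sided Student t-test (pooled variance by default,
    Welch via ``equal_var=False``) between responders and poor
    responders, and the log2 fold-change of group means.  For ΔCt input
    the values are already log2-scale, so the fold-change is the plain
    difference of group means; for intensities/normalized counts it is
    log2 of the ratio of linear-scale means (``fc_scale="log"`` averages
    on the log scale instead).

    Candidates absent from the matrix are reported with
    ``measured=False`` rather than raising.  Genes with zero variance in
    both groups get p = 1 and ``degenerate=True``.

    Returns a DataFrame indexed by gene with columns
    t_statistic, p_value, log2_fold_change, measured, degenerate.
    """
    if not isinstance(genes, TargetGeneSet):
        genes = TargetGeneSet(tuple(genes))
    if isinstance(matrix, DeltaCtTable):
        data, log2_input = matrix.data, True
    else:
        if not matrix.normalized:
            raise DataError("differential expression requires a normalized matrix")
        data, log2_input = matrix.data, False
    if fc_scale not in ("linear", "log"):
        raise DataError(f"fc_scale must be 'linear' or 'log', got {fc_scale!r}")
    resp, poor = _group_values(data, annotation)

    rows = []
    for gene in genes.gene_ids:
        if gene not in data.index:
            rows.append((gene, np.nan, np.nan, np.nan, False, False))
            continue
        x = resp.loc[gene].to_numpy(dtype=float)
        y = poor.loc[gene].to_numpy(dtype=float)
        degenerate = x.std() == 0 and y.std() == 0
        if degenerate:
            t_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                # near-identical groups (common after quantile normalization)
                # trip scipy's precision warning; exact degeneracy is already
                # flagged above
                warnings.filterwarnings("ignore", message="Precision loss")
                t_stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
        if log2_input:
            lfc = x.mean() - y.mean()
        elif fc_scale == "log":
            with np.errstate(divide="ignore", invalid="ignore"):
                lfc = np.log2(x).mean() - np.log2(y).mean()
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                lfc = np.log2(x.mean() / y.mean())
        rows.append((gene, float(t_stat), float(p), float(lfc), True, degenerate))
    return pd.DataFrame(
        rows,
        columns=["gene", "t_statistic", "p_value", "log2_fold_change", "measured", "degenerate"],
    ).set_index("gene")


def select_signature(
    de: pd.DataFrame, genes: TargetGeneSet | Iterable[str]
) -> SignatureDefinition:
    """Directionality rule: keep candidates up-regulated in responders.

    A candidate is included iff it was measured and its log2 fold-change
    (responders vs poor responders) is strictly positive; down-regulated
    and unmeasured candidates are excluded with an explicit verdict.
    """
    if not isinstance(genes, TargetGeneSet):
        genes = TargetGeneSet(tuple(genes))
    verdicts: dict[str, Verdict] = {}
    final: list[str] = []
    has_measured = "measured" in de.columns
    for gene in genes.gene_ids:
        if gene not in de.index or (has_measured and not bool(de.loc[gene, "measured"])):
            verdicts[gene] = Verdict.EXCLUDED_MISSING
        elif float(de.loc[gene, "log2_fold_change"]) > 0:
            verdicts[gene] = Verdict.INCLUDED
            final.append(gene)
        else:
            verdicts[gene] = Verdict.EXCLUDED_DOWNREGULATED
    if not final:
        raise DegenerateDataError("no candidate gene is up-regulated in responders; empty signature")
    return SignatureDefinition(candidates=genes.gene_ids, verdicts=verdicts, genes=tuple(final))


def default_epsilon(platform: Platform) -> float:
    """Pseudocount added before log10: 1 for normalized RNA-seq values
    (zeros occur), 0 for microarray intensities (positive by construction)."""
    return 1.0 if platform is Platform.RNASEQ_COUNTS else 0.0


def score_samples(
    matrix: Union[ExpressionMatrix, DeltaCtTable],
    signature: SignatureDefinition,
    epsilon: float | None = None,
) -> ScoreSet:
    """Additive signature score per sample.

    Intensity/count platforms: score(s) = Σ_g log10(x(g, s) + ε) over the
    signature genes.  qPCR: score(s) = Σ_g ΔCt(g, s).  A signature gene
    absent from the matrix is a hard error: the score is an unweighted
    sum and is not comparable across different gene counts.
    """
    genes = list(signature.genes)
    if isinstance(matrix, DeltaCtTable):
        missing = [g for g in genes if g not in matrix.data.index]
        if missing:
            raise DataError(f"signature genes absent from ΔCt table: {missing}")
        scores = matrix.data.loc[genes].sum(axis=0)
        return ScoreSet(
            scores.rename("score"), Platform.PCR_CT, tuple(genes), epsilon=0.0
        )
    if not matrix.normalized:
        raise DataError("scoring requires a normalized matrix")
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise DataError(f"signature genes absent from matrix: {missing}")
    if epsilon is None:
        epsilon = default_epsilon(matrix.platform)
    values = matrix.data.loc[genes].to_numpy(dtype=float) + epsilon
    if (values <= 0).any():
        raise DataError(
            "non-positive expression after pseudocount; raise epsilon or check normalization"
        )
    scores = pd.Series(
        np.log10(values).sum(axis=0), index=matrix.data.columns, name="score"
    )
    return ScoreSet(scores, matrix.platform, tuple(genes), epsilon=float(epsilon))


def save_signature(signature: SignatureDefinition, path: Union[str, Path],
                   platform: Platform | None = None, epsilon: float | None = None) -> None:
    """Serialize a signature as a small key-value text file so a scored
    cohort is reproducible bit-for-bit."""
    payload = {
        "genes": list(signature.genes),
        "candidates": list(signature.candidates),
        "verdicts": {g: v.value for g, v in signature.verdicts.items()},
    }
    if platform is not None:
        payload["platform"] = Platform(platform).value
    if epsilon is not None:
        payload["epsilon"] = float(epsilon)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def load_signature(path: Union[str, Path]) -> tuple[SignatureDefinition, dict]:
    """Load a serialized signature; returns (definition, metadata) where
    metadata carries optional platform/epsilon keys."""
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        genes = tuple(payload["genes"])
        candidates = tuple(payload.get("candidates", genes))
        verdicts = {
            g: Verdict(v) for g, v in payload.get(
                "verdicts", {g: Verdict.INCLUDED.value for g in genes}
            ).items()
        }
    except (KeyError, TypeError) as exc:
        raise DataError(f"malformed signature file {path}: {exc}") from exc
    meta = {k: payload[k] for k in ("platform", "epsilon") if k in payload}
    return SignatureDefinition(candidates=candidates, verdicts=verdicts, genes=genes), meta
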