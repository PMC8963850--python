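"""Cell-line panel validation of the signature.

Three analyses against a drug-screened cell-line panel (score per line,
log10 IC50 in µM, and a binary gene x line mutation matrix):

* Spearman correlation of signature score with log10 IC50 — since low
  IC50 means high drug sensitivity, a useful response signature should
  correlate *negatively*;
* extreme-responder classification — the most sensitive (bottom
  fraction by IC50) lines are labeled responders, the most resistant
  (top fraction) poor responders, the middle is discarded, and the
  score's AUC for that label is computed;
* per-gene mutation association — two-sided Mann-Whitney U of IC50
  between mutant and wild-type lines, Benjamini-Hochberg FDR across the
  tested genes, significance = FDR < 0.1 and more than 2-fold IC50
  difference (|mean log2 IC50 difference| > 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateDataError
from .evaluation import ROCResult, roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "CellLinePanel",
    "load_panel",
    "score_ic50_correlation",
    "extreme_classification",
    "mutation_association",
]

LOG2_PER_LOG10 = 1.0 / np.log10(2.0)


@dataclass
class CellLinePanel:
    """Per-line signature score, log10 IC50 (µM) and optional binary
    mutation matrix (genes x lines, 1 = altered)."""

    scores: pd.Series
    log10_ic50: pd.Series
    mutations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.log10_ic50.index):
            self.log10_ic50 = self.log10_ic50.reindex(self.scores.index)
        if self.scores.isna().any() or self.log10_ic50.isna().any():
            raise DataError("panel has missing score or IC50 values")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise DataError("non-finite score in panel")
        if not np.isfinite(self.log10_ic50.to_numpy(dtype=float)).all():
            raise DataError("non-finite log10 IC50 in panel")
        if self.mutations is not None:
            m = self.mutations.reindex(columns=self.scores.index)
            if m.isna().any().any():
                raise DataError("mutation matrix does not cover every panel line")
            values = m.to_numpy()
            if not np.isin(values, (0, 1)).all():
                raise DataError("mutation matrix must be binary (0/1)")
            self.mutations = m.astype(int)

    @property
    def line_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


def load_panel(
    panel_path: Union[str, Path], mutations_path: Union[str, Path, None] = None
) -> CellLinePanel:
    """Load a panel table (columns line_id, score, log10_ic50; TSV or CSV)
    and, optionally, a genes x lines 0/1 mutation matrix."""
    path = Path(panel_path)
    sep = "\t" if "\t" in path.open(encoding="utf-8").readline() else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("line_id", "score", "log10_ic50") if c not in df.columns]
    if missing:
        raise DataError(f"panel table missing column(s): {missing}")
    df = df.set_index("line_id")
    mutations = None
    if mutations_path is not None:
        mpath = Path(mutations_path)
        msep = "\t" if "\t" in mpath.open(encoding="utf-8").readline() else ","
        mutations = pd.read_csv(mpath, sep=msep, index_col=0)
    return CellLinePanel(df["score"], df["log10_ic50"], mutations)


def score_ic50_correlation(panel: CellLinePanel) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) of score vs log10 IC50,
    with a two-sided p-value from the large-sample t approximation."""
    if len(panel) < 4:
        raise DegenerateDataError("correlation needs at least 4 cell lines")
    s = panel.scores.to_numpy(dtype=float)
    ic = panel.log10_ic50.to_numpy(dtype=float)
    if np.ptp(s) == 0 or np.ptp(ic) == 0:
        raise DegenerateDataError("constant score or IC50; correlation undefined")
    rho, p = stats.spearmanr(s, ic)
    return float(rho), float(p)


def extreme_classification(panel: CellLinePanel, fraction: float = 0.05) -> ROCResult:
    """AUC of the score for separating the IC50 extremes.

    The ``fraction`` most sensitive lines (lowest IC50) are labeled
    responders, the same number of most resistant lines poor responders;
    everything in between is discarded.  Ties at the quantile boundary
    are broken by a stable sort on line id.
    """
    if not 0 < fraction < 0.5:
        raise DataError(f"tail fraction must be in (0, 0.5), got {fraction}")
    n = len(panel)
    k = int(np.floor(fraction * n))
    if k < 1:
        raise DegenerateDataError(
            f"panel of {n} lines leaves no line in a {fraction:.0%} tail"
        )
    order = panel.log10_ic50.sort_values(kind="stable").index
    bottom = list(order[:k])   # most sensitive -> responders
    top = list(order[-k:])     # most resistant -> poor responders
    scores = pd.concat([panel.scores[bottom], panel.scores[top]])
    labels = pd.Series([True] * k + [False] * k, index=scores.index)
    return roc_auc(scores, labels)


def mutation_association(panel: CellLinePanel, min_altered: int = 3,
                         fdr_threshold: float = 0.1,
                         effect_threshold: float = 1.0) -> pd.DataFrame:
    """Per-gene association of mutation status with drug sensitivity.

    For each gene with at least ``min_altered`` mutant *and* wild-type
    lines: two-sided Mann-Whitney U on IC50 between the groups (exact
    when both groups have <= 20 tie-free values, normal approximation
    with tie/continuity correction otherwise), BH-FDR across tested
    genes, and an effect size defined as the difference of group means
    of log2-transformed IC50 (mutant - wild-type), so |effect| > 1 means
    a more-than-2-fold IC50 difference.  ``significant`` requires both
    FDR < ``fdr_threshold`` and |effect| > ``effect_threshold``.
    """
    if panel.mutations is None:
        raise DataError("panel has no mutation matrix")
    ic50_log2 = panel.log10_ic50.to_numpy(dtype=float) * LOG2_PER_LOG10
    rows = []
    for gene, row in panel.mutations.iterrows():
        altered = row.to_numpy(dtype=int).astype(bool)
        n_mut, n_wt = int(altered.sum()), int((~altered).sum())
        if n_mut < min_altered or n_wt < min_altered:
            continue
        mut, wt = ic50_log2[altered], ic50_log2[~altered]
        method = "exact" if (
            n_mut <= 20 and n_wt <= 20 and len(np.unique(np.concatenate([mut, wt]))) == n_mut + n_wt
        ) else "asymptotic"
        _, p = stats.mannwhitneyu(mut, wt, alternative="two-sided", method=method)
        rows.append((gene, float(mut.mean() - wt.mean()), float(p), n_mut))
    if not rows:
        warnings.warn("no gene passes the min_altered filter; empty association table")
        return pd.DataFrame(
            columns=["effect_size", "p_value", "fdr", "n_altered", "significant"]
        )
    table = pd.DataFrame(
        rows, columns=["gene", "effect_size", "p_value", "n_altered"]
    ).set_index("gene")
    table["fdr"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = (table["fdr"] < fdr_threshold) & (
        table["effect_size"].abs() > effect_threshold
    )
    return table[["effect_size", "p_value", "fdr", "n_altered", "significant"]]
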