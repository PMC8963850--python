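"""Replicate simulation experiments.

Helpers that wire the generator to the pipeline for power / calibration
studies: per-replicate signature AUC on independent validation cohorts,
and mutation-association flag rates on simulated panels.  Used by the
test suite and the acceptance script; exposed because they answer the
questions a user of the synthetic generator will ask anyway ("what AUC
should I expect at this effect size and sample size?").
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .evaluation import roc_auc
from .invitro import mutation_association
from .normalization import normalize
from .signature import differential_expression, score_samples, select_signature
from .synthetic import CohortSimSpec, PanelSimSpec, simulate_cohort, simulate_panel

__all__ = [
    "signature_auc_replicates",
    "mutation_flag_replicates",
]


def _normalized(spec: CohortSimSpec, seed: int):
    matrix, annotation = simulate_cohort(replace(spec, seed=seed))
    return normalize(matrix, housekeeping=spec.housekeeping), annotation


def signature_auc_replicates(
    spec: CohortSimSpec, n_replicates: int, seed: int = 0
) -> pd.DataFrame:
    """Discovery/validation AUC per replicate.

    Each replicate simulates an independent discovery cohort (signature
    selection: normalize -> differential expression -> directionality
    rule) and an independent validation cohort from the same spec, then
    reports the signature's out-of-sample AUC next to each candidate
    gene's single-gene AUC on the same validation cohort.  Selecting and
    evaluating on separate cohorts keeps the null calibration honest: a
    signature chosen on the scored data itself would look better than
    chance even with no real signal.

    Returns one row per replicate: ``signature_auc``, ``n_genes`` and an
    ``auc_<gene>`` column per candidate.  Replicates where no candidate
    passes the selection rule (possible under a null spec) get NaN.
    """
    candidates = list(spec.effects)
    records = []
    for i in range(n_replicates):
        disc_seed, val_seed = seed + 2 * i, seed + 2 * i + 1
        disc, disc_ann = _normalized(spec, disc_seed)
        val, val_ann = _normalized(spec, val_seed)
        row = {}
        try:
            de = differential_expression(disc, disc_ann, candidates)
            sig = select_signature(de, candidates)
            scores = score_samples(val, sig)
            row["signature_auc"] = roc_auc(scores, val_ann).auc
            row["n_genes"] = len(sig.genes)
        except DegenerateDataError:
            row["signature_auc"] = np.nan
            row["n_genes"] = 0
        val_data = val.data
        for gene in candidates:
            if gene in val_data.index:
                row[f"auc_{gene}"] = roc_auc(val_data.loc[gene], val_ann).auc
        records.append(row)
    return pd.DataFrame.from_records(records)


def mutation_flag_replicates(
    spec: PanelSimSpec,
    n_replicates: int,
    seed: int = 0,
    permute: bool = False,
    min_altered: int = 3,
) -> pd.DataFrame:
    """Mutation-association outcomes over replicate panels.

    Per replicate: simulate a panel, optionally permute IC50 across
    lines (destroying every association; the permutation null), run the
    Mann-Whitney/FDR screen, and record for each spec'd mutation gene
    whether it was flagged and its estimated effect, plus the total
    number of flagged genes.
    """
    genes = [m.gene for m in spec.mutations]
    records = []
    for i in range(n_replicates):
        panel = simulate_panel(replace(spec, seed=seed + i))
        if permute:
            rng = np.random.default_rng(np.random.SeedSequence([seed + i, 97]))
            shuffled = panel.log10_ic50.to_numpy().copy()
            rng.shuffle(shuffled)
            panel.log10_ic50 = pd.Series(
                shuffled, index=panel.log10_ic50.index, name="log10_ic50"
            )
        table = mutation_association(panel, min_altered=min_altered)
        row = {"n_flagged": int(table["significant"].sum())}
        for gene in genes:
            if gene in table.index:
                row[f"flagged_{gene}"] = bool(table.loc[gene, "significant"])
                row[f"effect_{gene}"] = float(table.loc[gene, "effect_size"])
        records.append(row)
    return pd.DataFrame.from_records(records)
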