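"""Peptide-level target-decoy FDR estimation and threshold selection.

The estimator is the canonical decoy-count ratio: at a score cutoff ``c`` the
FDR among accepted target peptides is estimated as

    FDR(c) = #{decoy peptides with score >= c} / #{target peptides with score >= c}

assuming equal-size target and decoy databases and no pi0 correction.
Threshold selection scans the observed target scores and accepts everything at
or above the smallest score whose estimated FDR does not exceed ``alpha``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["collapse_to_peptides", "fdr_at_cutoff", "threshold_for_fdr", "fdr_sweep"]

PSM_COLUMNS = ["peptide", "score", "is_decoy", "protein", "sample"]


def collapse_to_peptides(psms: pd.DataFrame) -> pd.DataFrame:
    """Collapse PSMs to peptide-level records.

    One output row per distinct ``(peptide, is_decoy)`` pair, keeping the best
    (maximum) score and the metadata of the best-scoring PSM. Target and decoy
    populations are preserved separately; an empty input yields an empty frame.
    """
    if len(psms) == 0:
        return psms.copy()
    idx = (
        psms.sort_values("score", kind="mergesort")
        .groupby(["peptide", "is_decoy"], sort=False)
        .tail(1)
        .index
    )
    out = psms.loc[idx].sort_values(
        ["is_decoy", "score", "peptide"], ascending=[True, False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def _split(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    is_decoy = records["is_decoy"].to_numpy(dtype=bool)
    scores = records["score"].to_numpy(dtype=float)
    return np.sort(scores[~is_decoy]), np.sort(scores[is_decoy])


def fdr_at_cutoff(peptide_records: pd.DataFrame, score_cutoff: float) -> float:
    """Estimated FDR among target records with score >= ``score_cutoff``.

    Returns 0.0 when no target record passes the cutoff.
    """
    if not math.isfinite(score_cutoff):
        raise InvalidArgumentError("score_cutoff must be finite")
    targets, decoys = _split(peptide_records)
    n_t = targets.size - np.searchsorted(targets, score_cutoff, side="left")
    if n_t == 0:
        return 0.0
    n_d = decoys.size - np.searchsorted(decoys, score_cutoff, side="left")
    return float(n_d) / float(n_t)


def threshold_for_fdr(
    peptide_records: pd.DataFrame, alpha: float
) -> tuple[float, pd.DataFrame]:
    """Smallest observed target score whose estimated FDR is <= ``alpha``.

    Returns ``(cutoff, accepted)`` where ``accepted`` contains the target
    peptide records at or above the cutoff (ties at the cutoff are all
    accepted). If no observed target score satisfies ``alpha``, the cutoff is
    ``math.inf`` and the accepted set is empty.
    """
    if not 0.0 < alpha <= 1.0:
        raise InvalidArgumentError(f"alpha must lie in (0, 1], got {alpha}")
    targets_df = peptide_records.loc[~peptide_records["is_decoy"].astype(bool)]
    targets, decoys = _split(peptide_records)
    if targets.size == 0:
        return math.inf, targets_df.iloc[0:0]
    candidates = np.unique(targets)  # ascending
    n_t = targets.size - np.searchsorted(targets, candidates, side="left")
    n_d = decoys.size - np.searchsorted(decoys, candidates, side="left")
    ok = (n_d / n_t) <= alpha
    if not ok.any():
        return math.inf, targets_df.iloc[0:0]
    cutoff = float(candidates[np.argmax(ok)])
    accepted = targets_df.loc[targets_df["score"] >= cutoff]
    return cutoff, accepted.reset_index(drop=True)


def fdr_sweep(
    peptide_records: pd.DataFrame, alphas
) -> list[tuple[float, float, pd.DataFrame]]:
    """Run :func:`threshold_for_fdr` over an ascending grid of thresholds.

    Returns ``[(alpha, cutoff, accepted), ...]``. Accepted sets are nested:
    the cutoff is non-increasing in ``alpha`` because the feasible cutoff set
    only grows as ``alpha`` grows.
    """
    alphas = list(alphas)
    if any(not 0.0 < a <= 1.0 for a in alphas):
        raise InvalidArgumentError("each alpha must lie in (0, 1]")
    if any(a2 <= a1 for a1, a2 in zip(alphas, alphas[1:])):
        raise InvalidArgumentError("alphas must be sorted strictly ascending")
    return [(a, *threshold_for_fdr(peptide_records, a)) for a in alphas]
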