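"""FDR-sweep curves, protein-of-interest filtering, and low/high-input rescue.

``build_sweep`` assembles, per FDR threshold, the three counts a sweep figure
plots -- total accepted peptides, accepted 9-11mers, predicted binders among
them -- together with the binder percentage. ``rescue_analysis`` evaluates the
fate of *band* peptides (binders accepted only between a strict and a relaxed
threshold in a low-input sample) in a higher-input sample of the same
material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import strip_accession
from .binding import SUPPORTED_LENGTHS, binder_peptides
from .errors import InvalidArgumentError
from .fdr import collapse_to_peptides, fdr_sweep

__all__ = ["SweepResult", "build_sweep", "filter_by_source", "RescueReport", "rescue_analysis"]


@dataclass
class SweepResult:
    """Sweep points plus the underlying accepted/binder sets per threshold.

    ``points`` columns: ``fdr_threshold, score_cutoff, n_total_peptides,
    n_9_11, n_binders, pct_binders``. ``pct_binders`` is NaN (a tagged missing
    value, never 0) when no 9-11mers were accepted.
    """

    points: pd.DataFrame
    accepted_by_alpha: dict[float, pd.DataFrame] = field(repr=False)
    binders_by_alpha: dict[float, set] = field(repr=False)

    def nine_to_eleven(self, alpha: float) -> list[str]:
        acc = self.accepted_by_alpha[alpha]
        return [p for p in acc["peptide"] if len(p) in SUPPORTED_LENGTHS]


def build_sweep(psms: pd.DataFrame, profiles, alphas) -> SweepResult:
    """Threshold sweep: FDR filter -> 9-11mer filter -> multi-allele binder call."""
    records = collapse_to_peptides(psms)
    rows = []
    accepted_by_alpha: dict[float, pd.DataFrame] = {}
    binders_by_alpha: dict[float, set] = {}
    for alpha, cutoff, accepted in fdr_sweep(records, alphas):
        peptides = list(accepted["peptide"])
        mers = [p for p in peptides if len(p) in SUPPORTED_LENGTHS]
        binders = binder_peptides(profiles, mers) if mers else set()
        n_mers = len(set(mers))
        rows.append(
            {
                "fdr_threshold": alpha,
                "score_cutoff": cutoff,
                "n_total_peptides": len(set(peptides)),
                "n_9_11": n_mers,
                "n_binders": len(binders),
                "pct_binders": 100.0 * len(binders) / n_mers if n_mers else math.nan,
            }
        )
        accepted_by_alpha[alpha] = accepted
        binders_by_alpha[alpha] = binders
    return SweepResult(pd.DataFrame(rows), accepted_by_alpha, binders_by_alpha)


def filter_by_source(sweep: SweepResult, accession_list) -> pd.DataFrame:
    """Accepted binder peptides per threshold restricted to proteins of interest.

    ``accession_list`` is e.g. a panel of tumour-associated antigens.
    Accessions are compared after database-prefix stripping. Returns one row
    per threshold with the count and the peptides; counts are non-decreasing
    in the threshold because accepted sets are nested.
    """
    wanted = {strip_accession(a) for a in accession_list}
    if not wanted:
        raise InvalidArgumentError("accession_list must not be empty")
    rows = []
    for alpha, accepted in sorted(sweep.accepted_by_alpha.items()):
        binders = sweep.binders_by_alpha[alpha]
        mask = accepted["peptide"].isin(binders) & accepted["protein"].map(
            lambda a: strip_accession(str(a)) in wanted
        )
        peptides = sorted(set(accepted.loc[mask, "peptide"]))
        rows.append(
            {"fdr_threshold": alpha, "n_poi_binders": len(peptides), "peptides": ";".join(peptides)}
        )
    return pd.DataFrame(rows)


@dataclass
class RescueReport:
    """Fate of relaxed-band binders from a low-input sample in a high-input one.

    ``band_binders`` are the predicted binders among 9-11mers accepted at the
    relaxed but not the strict threshold in the low-input sample;
    ``n_recovered_strict`` of them reappear in the high-input sample already
    at the strict threshold, ``n_recovered_relaxed_extra`` only in its
    relaxed-minus-strict band. ``recovery_fraction`` is NaN when the band is
    empty.
    """

    alpha_strict: float
    alpha_relaxed: float
    band_binders: set[str]
    n_band: int
    n_recovered_strict: int
    n_recovered_relaxed_extra: int
    recovery_fraction: float

    def to_dict(self) -> dict:
        return {
            "alpha_strict": self.alpha_strict,
            "alpha_relaxed": self.alpha_relaxed,
            "n_band": self.n_band,
            "n_recovered_strict": self.n_recovered_strict,
            "n_recovered_relaxed_extra": self.n_recovered_relaxed_extra,
            "recovery_fraction": None if math.isnan(self.recovery_fraction) else self.recovery_fraction,
            "band_binders": sorted(self.band_binders),
        }


def rescue_analysis(
    low_psms: pd.DataFrame,
    high_psms: pd.DataFrame,
    profiles,
    alpha_strict: float,
    alpha_relaxed: float,
) -> RescueReport:
    """Recovery of low-input relaxed-band binders in a high-input sample.

    Binder status is evaluated once, in the low-input sample; the high-input
    lookup matches on exact sequence (I/L kept distinct).
    """
    if alpha_strict >= alpha_relaxed:
        raise InvalidArgumentError("alpha_strict must be smaller than alpha_relaxed")
    low = build_sweep(low_psms, profiles, [alpha_strict, alpha_relaxed])
    strict_set = set(low.accepted_by_alpha[alpha_strict]["peptide"])
    relaxed_mers = set(low.nine_to_eleven(alpha_relaxed))
    band = (relaxed_mers - strict_set) & low.binders_by_alpha[alpha_relaxed]

    high_records = collapse_to_peptides(high_psms)
    (_, _, high_strict), (_, _, high_relaxed) = [
        (a, c, acc) for a, c, acc in fdr_sweep(high_records, [alpha_strict, alpha_relaxed])
    ]
    high_strict_set = set(high_strict["peptide"])
    high_relaxed_set = set(high_relaxed["peptide"])

    recovered_strict = band & high_strict_set
    recovered_extra = band & (high_relaxed_set - high_strict_set)
    n_band = len(band)
    return RescueReport(
        alpha_strict=alpha_strict,
        alpha_relaxed=alpha_relaxed,
        band_binders=band,
        n_band=n_band,
        n_recovered_strict=len(recovered_strict),
        n_recovered_relaxed_extra=len(recovered_extra),
        recovery_fraction=len(recovered_strict) / n_band if n_band else math.nan,
    )
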