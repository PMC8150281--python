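"""Negative controls for HLA-binding enrichment.

Two controls, mirroring standard practice in ligandome studies:

* a *scrambled* dataset -- same number of peptides, same length multiset and
  exactly the same pooled amino-acid composition as the input, obtained by
  pooling all residues, permuting them, and re-partitioning into the original
  length sequence;
* a *mismatch* control -- binder calling of the identified peptides against
  an HLA allele the source cells do not express (anchor preferences disjoint
  from the expressed alleles).

Both should yield binder fractions at (or below) the chance rate of
composition-matched random peptides; a fraction clearly above chance would
indicate the binding predictor is responding to dataset composition rather
than genuine motif content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import decode, encode
from .binding import binder_peptides
from .errors import InvalidArgumentError
from .rng import substream

__all__ = [
    "scramble_dataset",
    "chance_binder_rate",
    "ControlPoint",
    "binder_fraction_control",
    "mismatch_control",
]

_CONTROL_LENGTHS = (9, 10, 11)


def scramble_dataset(peptides, seed: int) -> list[str]:
    """Dataset-level scramble of a 9-11mer peptide set.

    Pools every residue of the input, randomly permutes the pool, and
    re-partitions it into the original lengths in their original order. The
    output therefore conserves the peptide count, the length multiset and the
    pooled residue multiset exactly.
    """
    peptides = list(peptides)
    lengths = [len(p) for p in peptides]
    if any(ln not in _CONTROL_LENGTHS for ln in lengths):
        raise InvalidArgumentError("scramble_dataset requires 9-11mer peptides")
    if not peptides:
        return []
    rng = substream(seed, "scramble")
    pool = rng.permutation(encode("".join(peptides)))
    out = []
    pos = 0
    for ln in lengths:
        out.append(decode(pool[pos : pos + ln]))
        pos += ln
    return out


def chance_binder_rate(
    profiles, peptides, n_samples: int, seed: int
) -> tuple[float, int]:
    """Monte-Carlo binder chance rate for composition-matched random peptides.

    Draws ``n_samples`` peptides whose lengths follow the input's length
    multiset and whose residues are i.i.d. from the input's pooled residue
    frequencies, and returns ``(binder fraction, n_samples)``.
    """
    peptides = list(peptides)
    if not peptides:
        raise InvalidArgumentError("cannot estimate a chance rate from an empty peptide set")
    rng = substream(seed, "chance")
    pool = encode("".join(peptides))
    freqs = np.bincount(pool, minlength=20).astype(float)
    freqs /= freqs.sum()
    lengths = np.array([len(p) for p in peptides])
    drawn_lengths = rng.choice(lengths, size=n_samples)
    total = int(drawn_lengths.sum())
    residues = rng.choice(20, size=total, p=freqs)
    randoms = []
    pos = 0
    for ln in drawn_lengths:
        randoms.append(decode(residues[pos : pos + ln]))
        pos += ln
    # duplicates among random peptides are astronomically rare but binder
    # calling dedups, so count per draw explicitly
    binders = binder_peptides(profiles, randoms)
    k = sum(1 for p in randoms if p in binders)
    return k / n_samples, n_samples


@dataclass
class ControlPoint:
    """Binder fraction of one peptide set under one allele panel."""

    fdr_threshold: float
    n_peptides: int
    n_binders: int
    fraction: float  # 0 when the set is empty; see ``is_empty``
    is_empty: bool

    @classmethod
    def from_set(cls, alpha: float, peptides, profiles) -> "ControlPoint":
        peptides = list(dict.fromkeys(peptides))
        if not peptides:
            return cls(alpha, 0, 0, 0.0, True)
        binders = binder_peptides(profiles, peptides)
        n = len(peptides)
        return cls(alpha, n, len(binders), len(binders) / n, False)


def binder_fraction_control(profiles, peptide_sets_by_alpha: dict) -> pd.DataFrame:
    """Binder fraction per FDR threshold for an arbitrary allele panel.

    ``peptide_sets_by_alpha`` maps each FDR threshold to its accepted 9-11mer
    peptides. Empty sets are reported with ``fraction = 0`` and an explicit
    ``is_empty`` marker rather than dropped.
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidArgumentError("at least one allele profile is required")
    rows = [
        ControlPoint.from_set(alpha, peps, profiles)
        for alpha, peps in sorted(peptide_sets_by_alpha.items())
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def mismatch_control(profiles_mismatch, peptide_sets_by_alpha: dict) -> pd.DataFrame:
    """Binder fraction per FDR threshold against mismatched (unexpressed) alleles."""
    return binder_fraction_control(profiles_mismatch, peptide_sets_by_alpha)
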