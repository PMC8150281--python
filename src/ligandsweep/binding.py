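"""Position-specific scoring matrix (PSSM) HLA class I binding predictor.

Per allele and per supported length (9, 10, 11) a PSSM of per-position,
per-residue log-odds-like weights is summed over the peptide to give a raw
score. Two derived quantities reproduce the output contract of the NetMHC
family of tools:

* ``percent_rank`` -- the raw score's rank within a large random-peptide
  background, in percent (ties counted as >=);
* ``ic50`` -- ``50000 ** (1 - s)`` nM on an affine-normalised score
  ``s = clamp((raw - score_min) / (score_max - score_min), 0, 1)``.

``score_min``/``score_max`` are calibrated per length from the background so
that the background median maps to ~30000 nM (non-binding) and the top-2%
background quantile maps to 500 nM. This aligns the two conventional binder
criteria -- IC50 <= 500 nM, percent rank <= 2% -- at the same operating point,
mirroring the weak-binder convention of affinity predictors. A peptide is a
binder if either criterion holds (inclusive OR); at the dataset level a
peptide binds if it binds any supplied allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, N_RESIDUES, decode, encode, encode_many
from .errors import ConfigurationError, InvalidArgumentError, LengthError
from .rng import substream
from .simulate import AlleleSpec

__all__ = [
    "AlleleProfile",
    "build_profile",
    "build_profiles",
    "score_peptide",
    "ic50_from_score",
    "percent_rank",
    "call_binders",
    "binder_peptides",
    "IC50_BINDER_NM",
    "RANK_BINDER_PCT",
    "SUPPORTED_LENGTHS",
]

SUPPORTED_LENGTHS = (9, 10, 11)
IC50_BINDER_NM = 500.0
RANK_BINDER_PCT = 2.0

_IC50_MAX = 50000.0
# calibration points for the affine score normalisation (see module docstring)
_S_AT_TOP2 = 1.0 - math.log(500.0) / math.log(_IC50_MAX)      # ~0.4257
_S_AT_MEDIAN = 1.0 - math.log(30000.0) / math.log(_IC50_MAX)  # ~0.0472


@dataclass
class AlleleProfile:
    """Scoring profile of one HLA allele.

    ``pssm_by_length`` maps length -> (length, 20) weight matrix, residue
    columns in alphabetical one-letter order; ``background_by_length`` maps
    length -> raw scores of random background peptides, sorted descending;
    ``score_range_by_length`` maps length -> (score_min, score_max) for the
    IC50 transform.
    """

    allele: str
    pssm_by_length: dict[int, np.ndarray]
    background_by_length: dict[int, np.ndarray]
    score_range_by_length: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ln, mat in self.pssm_by_length.items():
            if mat.shape != (ln, N_RESIDUES):
                raise ConfigurationError(
                    f"PSSM for length {ln} must have shape ({ln}, {N_RESIDUES}), got {mat.shape}"
                )
        for ln, bg in self.background_by_length.items():
            if bg.size < 1000:
                raise ConfigurationError(f"background for length {ln} needs >= 1000 scores")
            if np.any(np.diff(bg) > 0):
                raise ConfigurationError("background scores must be sorted descending")


def _calibrate_range(bg_sorted_desc: np.ndarray) -> tuple[float, float]:
    q_median = float(np.quantile(bg_sorted_desc, 0.5))
    q_top2 = float(np.quantile(bg_sorted_desc, 0.98))
    if q_top2 <= q_median:
        raise ConfigurationError("degenerate background: cannot calibrate the IC50 transform")
    b = (_S_AT_TOP2 - _S_AT_MEDIAN) / (q_top2 - q_median)
    score_min = q_median - _S_AT_MEDIAN / b
    score_max = score_min + 1.0 / b
    return score_min, score_max


def build_profile(
    spec: AlleleSpec,
    seed: int,
    *,
    anchor_weight: float = 3.0,
    noise_sd: float = 0.25,
    n_background: int = 5000,
    profile_index: int = 0,
) -> AlleleProfile:
    """Construct an :class:`AlleleProfile` from an anchor-motif spec.

    The PSSM is small Gaussian position/residue preferences (sd ``noise_sd``)
    plus ``anchor_weight`` on the allowed residues at P2 and the C-terminal
    anchor; background scores come from ``n_background`` uniformly random
    peptides per length.
    """
    if n_background < 1000:
        raise InvalidArgumentError("n_background must be >= 1000")
    rng = substream(seed, "profiles", profile_index)
    pssms: dict[int, np.ndarray] = {}
    backgrounds: dict[int, np.ndarray] = {}
    ranges: dict[int, tuple[float, float]] = {}
    for ln in SUPPORTED_LENGTHS:
        mat = rng.normal(0.0, noise_sd, size=(ln, N_RESIDUES))
        for res in spec.p2:
            mat[1, AA_INDEX[res]] += anchor_weight
        for res in spec.cterm:
            mat[ln - 1, AA_INDEX[res]] += anchor_weight
        codes = rng.integers(0, N_RESIDUES, size=(n_background, ln))
        bg = np.sort(_score_codes(mat, codes))[::-1]
        pssms[ln] = mat
        backgrounds[ln] = bg
        ranges[ln] = _calibrate_range(bg)
    return AlleleProfile(spec.name, pssms, backgrounds, ranges)


def build_profiles(specs, seed: int, **kwargs) -> list[AlleleProfile]:
    """Build one profile per allele spec, each on its own substream of ``seed``."""
    return [
        build_profile(spec, seed, profile_index=i, **kwargs) for i, spec in enumerate(specs)
    ]


def _score_codes(pssm: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Sum PSSM weights over positions for an (n, L) residue-index matrix."""
    pos = np.arange(codes.shape[1])
    return pssm[pos, codes].sum(axis=1)


def score_peptide(profile: AlleleProfile, peptide: str) -> float:
    """Raw PSSM score: the sum over positions of the weight of each residue."""
    ln = len(peptide)
    if ln not in profile.pssm_by_length:
        raise LengthError(
            f"unsupported peptide length {ln}; profile supports {sorted(profile.pssm_by_length)}"
        )
    codes = encode(peptide)
    return float(_score_codes(profile.pssm_by_length[ln], codes[None, :])[0])


def ic50_from_score(raw_score, score_min: float, score_max: float):
    """Map a raw score to a predicted IC50 in nM.

    ``s = clamp((raw - score_min) / (score_max - score_min), 0, 1)`` and
    IC50 = ``50000 ** (1 - s)``; monotone decreasing in the raw score, with
    endpoints 50000 nM (s=0) and 1 nM (s=1).
    """
    if score_max <= score_min:
        raise InvalidArgumentError("score_max must exceed score_min")
    s = np.clip((np.asarray(raw_score, dtype=float) - score_min) / (score_max - score_min), 0.0, 1.0)
    out = _IC50_MAX ** (1.0 - s)
    return float(out) if np.isscalar(raw_score) else out


def percent_rank(profile: AlleleProfile, peptide: str) -> float:
    """Rank of the peptide's raw score within the background, in percent.

    ``100 * #{background >= raw score} / N_bg``; ties count as >=.
    """
    ln = len(peptide)
    if ln not in profile.background_by_length:
        raise ConfigurationError(f"no background scores for length {ln}")
    raw = score_peptide(profile, peptide)
    return float(_percent_rank_scores(profile, ln, np.array([raw]))[0])


def _percent_rank_scores(profile: AlleleProfile, length: int, raw: np.ndarray) -> np.ndarray:
    bg_asc = profile.background_by_length[length][::-1]  # ascending view
    n_ge = bg_asc.size - np.searchsorted(bg_asc, raw, side="left")
    return 100.0 * n_ge / bg_asc.size


def call_binders(profiles, peptides) -> pd.DataFrame:
    """Per-(peptide, allele) binding calls for the unique 9-11mer peptides.

    Peptides outside the supported lengths are excluded before calling.
    Returns a frame with columns ``peptide, allele, raw_score, ic50,
    percent_rank, is_binder``; a peptide is a dataset-level binder iff
    ``is_binder`` holds for at least one allele (see :func:`binder_peptides`).
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidArgumentError("at least one allele profile is required")
    uniq = pd.unique(pd.Series(list(peptides), dtype=object)) if len(list(peptides)) else []
    by_length: dict[int, list[str]] = {}
    for p in uniq:
        if len(p) in SUPPORTED_LENGTHS:
            by_length.setdefault(len(p), []).append(p)
    frames = []
    for ln, peps in sorted(by_length.items()):
        codes = encode_many(peps, ln)
        for prof in profiles:
            if ln not in prof.pssm_by_length:
                raise ConfigurationError(f"profile {prof.allele} lacks length {ln}")
            raw = _score_codes(prof.pssm_by_length[ln], codes)
            smin, smax = prof.score_range_by_length[ln]
            ic50 = ic50_from_score(raw, smin, smax)
            rank = _percent_rank_scores(prof, ln, raw)
            frames.append(
                pd.DataFrame(
                    {
                        "peptide": peps,
                        "allele": prof.allele,
                        "raw_score": raw,
                        "ic50": ic50,
                        "percent_rank": rank,
                        "is_binder": (ic50 <= IC50_BINDER_NM) | (rank <= RANK_BINDER_PCT),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["peptide", "allele", "raw_score", "ic50", "percent_rank", "is_binder"]
        )
    return pd.concat(frames, ignore_index=True)


def binder_peptides(profiles, peptides) -> set[str]:
    """Unique 9-11mer peptides binding at least one of the supplied alleles."""
    calls = call_binders(profiles, peptides)
    if len(calls) == 0:
        return set()
    return set(calls.loc[calls["is_binder"], "peptide"])
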