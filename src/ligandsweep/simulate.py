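"""Ground-truthed synthetic immunopeptidome experiments.

This module emulates the statistical structure of an HLA class I ligandome
LC-MS/MS experiment at the level the downstream analysis consumes: a scored
PSM table (targets plus decoys) over a synthetic proteome, with known ground
truth for every target PSM.

The generative model, briefly:

* a proteome of random protein sequences whose abundances are log-normal;
* true peptides are sampled from proteins with probability proportional to
  abundance, with a 9--11mer-dominated length mixture; a configurable fraction
  of them carries the anchor motif (P2 and C-terminal residue) of one of the
  cell's HLA alleles, written into the source protein so every true peptide is
  an exact proteome substring;
* each true peptide has a geometric copy number; its PSM score is
  ``score_shift_true + log2(input_scale * copy_number)`` plus unit Gaussian
  noise, so more input (more cells) shifts true scores up on a -10lgP-like
  axis while false/decoy scores stay put;
* false identifications are random sequences scored
  ``Normal(score_shift_false, 1)``; the decoy population is composition-
  preserving shuffles of target peptides, scored from the same distribution
  and equal in count to the false matches, which is what makes plain
  target-decoy FDR estimation unbiased on this simulator;
* an optional per-residue substitution channel models de novo sequencing
  errors, with error probability decreasing linearly in an ALC-like
  confidence score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .alphabet import AA_INDEX, AMINO_ACIDS, N_RESIDUES, decode, encode
from .errors import InvalidArgumentError
from .rng import substream

__all__ = [
    "AlleleSpec",
    "SimConfig",
    "Experiment",
    "MATCHED_ALLELES",
    "MISMATCH_ALLELES",
    "simulate_proteome",
    "simulate_experiment",
    "simulate_input_pair",
    "apply_denovo_noise",
]


@dataclass
class Experiment:
    """One simulated ligandome run.

    ``proteome`` is the searched database: the input proteome with the
    implanted anchor residues written into the source proteins, so that every
    true peptide is an exact substring of its source protein's sequence.
    """

    psms: pd.DataFrame
    truth: pd.DataFrame
    proteome: pd.DataFrame


class AlleleSpec(BaseModel):
    """Anchor-motif description of one HLA class I allele.

    ``p2`` and ``cterm`` list the residues tolerated at the second and the
    C-terminal anchor position; all other positions are unconstrained.
    """

    name: str
    p2: str
    cterm: str

    @field_validator("p2", "cterm")
    @classmethod
    def _canonical(cls, v: str) -> str:
        if not v or any(c not in AA_INDEX for c in v):
            raise ValueError(f"anchor residues must be non-empty canonical amino acids, got {v!r}")
        return v


#: Default "cell-expressed" alleles (A*02:01- and B*07:02-like anchor motifs).
MATCHED_ALLELES = [
    AlleleSpec(name="A*02:01", p2="LM", cterm="VI"),
    AlleleSpec(name="B*07:02", p2="PA", cterm="LF"),
]

#: Default mismatch allele: anchor preferences disjoint from both matched
#: alleles at both anchors, as required for a negative control.
MISMATCH_ALLELES = [AlleleSpec(name="A*03:01", p2="TS", cterm="KR")]

_DEFAULT_LENGTH_WEIGHTS = {8: 0.02, 9: 0.45, 10: 0.25, 11: 0.18, 12: 0.06, 13: 0.04}


class SimConfig(BaseModel):
    """Experimental knobs of one synthetic ligandome run."""

    n_proteins: int = Field(default=1000, ge=1)
    abundance_sigma: float = Field(default=2.0, ge=0.0)
    alleles: list[AlleleSpec] = Field(default_factory=lambda: [a.model_copy() for a in MATCHED_ALLELES])
    n_true_psms: int = Field(default=2000, ge=1)
    false_match_rate: float = Field(default=0.1, ge=0.0, lt=1.0)
    true_binder_fraction: float = Field(default=0.85, ge=0.0, le=1.0)
    length_weights: dict[int, float] = Field(default_factory=lambda: dict(_DEFAULT_LENGTH_WEIGHTS))
    input_scale: float = Field(default=1.0, gt=0.0)
    score_shift_true: float = 2.0
    score_shift_false: float = 0.0
    denovo_alc: float = Field(default=100.0, ge=0.0, le=100.0)
    seed: int = 0
    sample: str = "sim"

    @field_validator("length_weights")
    @classmethod
    def _weights_ok(cls, v: dict[int, float]) -> dict[int, float]:
        if not v:
            raise ValueError("length_weights must not be empty")
        if any(length < 8 or length > 13 for length in v):
            raise ValueError("length_weights keys must lie in 8..13")
        if any(w < 0 for w in v.values()):
            raise ValueError("length_weights must be non-negative")
        total = sum(v.values())
        if total == 0:
            raise ValueError("length_weights must not all be zero")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length_weights must sum to 1 (got {total})")
        return v

    @model_validator(mode="after")
    def _alleles_ok(self) -> "SimConfig":
        if not self.alleles:
            raise ValueError("at least one allele is required")
        return self


def simulate_proteome(
    n_proteins: int, abundance_sigma: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic proteome and its quantitative abundance table.

    Returns ``(proteome, abundance)``: ``proteome`` has columns
    ``accession, sequence`` (random sequences of length 100--1000) and
    ``abundance`` has columns ``accession, abundance`` with abundances drawn
    log-normal(0, ``abundance_sigma``), i.e. rankable with a realistic
    multi-order-of-magnitude spread.
    """
    if n_proteins < 1:
        raise InvalidArgumentError(f"n_proteins must be >= 1, got {n_proteins}")
    if abundance_sigma < 0:
        raise InvalidArgumentError("abundance_sigma must be non-negative")
    rng = substream(seed, "proteome")
    lengths = rng.integers(100, 1001, size=n_proteins)
    seqs = []
    for ln in lengths:
        seqs.append(decode(rng.integers(0, N_RESIDUES, size=int(ln))))
    width = max(4, len(str(n_proteins)))
    accessions = [f"SP{i:0{width}d}" for i in range(1, n_proteins + 1)]
    abundance = np.exp(rng.normal(0.0, abundance_sigma, size=n_proteins)) if abundance_sigma > 0 else np.ones(n_proteins)
    proteome = pd.DataFrame({"accession": accessions, "sequence": seqs})
    abundance_df = pd.DataFrame({"accession": accessions, "abundance": abundance})
    return proteome, abundance_df


def _assign_proteins(
    rng: np.random.Generator,
    lengths: np.ndarray,
    protein_lengths: np.ndarray,
    probs: np.ndarray,
) -> np.ndarray:
    """Assign each peptide a source protein (abundance-weighted) such that the
    total residue demand on every protein never exceeds its length."""
    n_prot = protein_lengths.size
    free = protein_lengths.astype(float).copy()
    draws = rng.choice(n_prot, p=probs, size=lengths.size)
    out = np.empty(lengths.size, dtype=np.intp)
    for i, ln in enumerate(lengths):
        g = draws[i]
        tries = 0
        while free[g] < ln and tries < 50:
            g = int(rng.choice(n_prot, p=probs))
            tries += 1
        if free[g] < ln:  # fall back to the emptiest protein
            g = int(np.argmax(free))
            if free[g] < ln:
                raise InvalidArgumentError("proteome too small for the requested number of PSMs")
        out[i] = g
        free[g] -= ln
    return out


def _place_windows(
    rng: np.random.Generator,
    lengths: np.ndarray,
    protein_of: np.ndarray,
    protein_lengths: np.ndarray,
) -> np.ndarray:
    """Choose a non-overlapping start position per peptide within its protein.

    Uses stars-and-bars gap sampling: the unoccupied residues of a protein are
    split into random gaps between consecutive windows, which yields random,
    mutually disjoint windows in one pass.
    """
    starts = np.empty(lengths.size, dtype=np.intp)
    for prot in np.unique(protein_of):
        members = np.flatnonzero(protein_of == prot)
        k = members.size
        slack = int(protein_lengths[prot] - lengths[members].sum())
        gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = int(gaps[0])
        for j, idx in enumerate(members):
            starts[idx] = pos
            pos += int(lengths[idx]) + int(gaps[j + 1])
    return starts


def simulate_experiment(
    config: SimConfig,
    proteome: pd.DataFrame,
    abundance: Optional[pd.DataFrame] = None,
    score_seed: Optional[int] = None,
) -> Experiment:
    """Simulate one ligandome experiment on a given proteome.

    Returns an :class:`Experiment` whose ``psms`` frame has columns
    ``peptide, score, is_decoy, protein, sample`` and whose ``truth`` frame
    has one row per target PSM with ``peptide, sample, is_true, is_binder,
    binder_allele, source_protein, copy_number``. Decoy PSMs carry no
    ground-truth record. ``Experiment.proteome`` is the searched database
    (anchor implants included); write this one to FASTA.

    ``score_seed`` re-draws only the score noise (a fresh MS acquisition of
    the same sample); the peptide skeleton -- which peptides, from which
    proteins, at which copy numbers -- is fully determined by ``config.seed``,
    so two configs differing only in ``input_scale`` share their skeleton and
    their score noise, and true scores shift by exactly
    ``log2(scale2/scale1)``.
    """
    if proteome is None or len(proteome) == 0:
        raise InvalidArgumentError("proteome must be non-empty")
    if not config.alleles:
        raise InvalidArgumentError("allele list must be non-empty")

    pep_rng = substream(config.seed, "peptides")
    score_rng = substream(config.seed if score_seed is None else score_seed, "scores")

    lengths_avail = np.array(sorted(config.length_weights), dtype=np.intp)
    length_probs = np.array([config.length_weights[int(k)] for k in lengths_avail], dtype=float)
    length_probs = length_probs / length_probs.sum()

    accessions = proteome["accession"].to_numpy()
    prot_codes = [encode(s) for s in proteome["sequence"]]
    prot_len = np.array([c.size for c in prot_codes], dtype=np.intp)

    if abundance is not None:
        ab = abundance.set_index("accession")["abundance"].reindex(accessions)
        if ab.isna().any():
            raise InvalidArgumentError("abundance table does not cover the proteome")
        probs = ab.to_numpy(dtype=float)
    else:
        probs = np.ones(accessions.size)
    probs = probs / probs.sum()

    n_true = config.n_true_psms
    f = config.false_match_rate
    n_false = int(round(n_true * f / (1.0 - f)))

    # -- true peptides ------------------------------------------------------
    true_lengths = pep_rng.choice(lengths_avail, p=length_probs, size=n_true)
    protein_of = _assign_proteins(pep_rng, true_lengths, prot_len, probs)
    starts = _place_windows(pep_rng, true_lengths, protein_of, prot_len)

    binder = pep_rng.random(n_true) < config.true_binder_fraction
    allele_idx = pep_rng.integers(0, len(config.alleles), size=n_true)
    # implant anchors into the *protein* so peptides remain exact substrings
    mutated: dict[int, np.ndarray] = {}
    p2_codes = [np.array([AA_INDEX[c] for c in a.p2]) for a in config.alleles]
    ct_codes = [np.array([AA_INDEX[c] for c in a.cterm]) for a in config.alleles]
    anchor_choice = pep_rng.random((n_true, 2))
    for i in range(n_true):
        if not binder[i]:
            continue
        prot = int(protein_of[i])
        if prot not in mutated:
            mutated[prot] = prot_codes[prot].copy()
        a = int(allele_idx[i])
        p2 = p2_codes[a][int(anchor_choice[i, 0] * p2_codes[a].size)]
        ct = ct_codes[a][int(anchor_choice[i, 1] * ct_codes[a].size)]
        seq = mutated[prot]
        seq[starts[i] + 1] = p2
        seq[starts[i] + int(true_lengths[i]) - 1] = ct

    true_peptides = []
    for i in range(n_true):
        seq = mutated.get(int(protein_of[i]), prot_codes[int(protein_of[i])])
        true_peptides.append(decode(seq[starts[i] : starts[i] + int(true_lengths[i])]))

    copy_number = pep_rng.geometric(0.5, size=n_true)

    # -- false matches (random sequences credited to a random DB protein) ---
    false_lengths = pep_rng.choice(lengths_avail, p=length_probs, size=n_false)
    false_peptides = [decode(pep_rng.integers(0, N_RESIDUES, size=int(ln))) for ln in false_lengths]
    false_protein = pep_rng.choice(accessions, size=n_false) if n_false else np.array([], dtype=object)

    # -- decoys: shuffled copies of target sequences, one per false match ---
    target_peptides = true_peptides + false_peptides
    decoy_src = pep_rng.integers(0, len(target_peptides), size=n_false)
    decoy_peptides = []
    for s in decoy_src:
        codes = encode(target_peptides[int(s)])
        decoy_peptides.append(decode(pep_rng.permutation(codes)))

    # -- scores -------------------------------------------------------------
    eps_true = score_rng.standard_normal(n_true)
    eps_false = score_rng.standard_normal(n_false)
    eps_decoy = score_rng.standard_normal(n_false)
    true_scores = config.score_shift_true + np.log2(config.input_scale * copy_number) + eps_true
    false_scores = config.score_shift_false + eps_false
    decoy_scores = config.score_shift_false + eps_decoy

    if config.denovo_alc < 100.0:
        true_peptides = apply_denovo_noise(true_peptides, config.denovo_alc, config.seed)

    sample = config.sample
    psms = pd.DataFrame(
        {
            "peptide": true_peptides + false_peptides + decoy_peptides,
            "score": np.concatenate([true_scores, false_scores, decoy_scores]),
            "is_decoy": [False] * (n_true + n_false) + [True] * n_false,
            "protein": list(accessions[protein_of]) + list(false_protein) + [""] * n_false,
            "sample": sample,
        }
    )
    truth = pd.DataFrame(
        {
            "peptide": true_peptides + false_peptides,
            "sample": sample,
            "is_true": [True] * n_true + [False] * n_false,
            "is_binder": list(binder) + [False] * n_false,
            "binder_allele": [
                config.alleles[int(a)].name if b else "" for a, b in zip(allele_idx, binder)
            ]
            + [""] * n_false,
            "source_protein": list(accessions[protein_of]) + [""] * n_false,
            "copy_number": list(copy_number) + [1] * n_false,
        }
    )
    if mutated:
        sequences = [
            decode(mutated[i]) if i in mutated else proteome["sequence"].iat[i]
            for i in range(len(proteome))
        ]
        proteome_out = pd.DataFrame({"accession": accessions, "sequence": sequences})
    else:
        proteome_out = proteome
    return Experiment(psms, truth, proteome_out)


def simulate_input_pair(
    config: SimConfig,
    proteome: pd.DataFrame,
    abundance: Optional[pd.DataFrame],
    high_input_scale: float,
    high_score_seed: Optional[int] = None,
) -> tuple[Experiment, Experiment]:
    """Simulate a low/high cell-input pair of the same underlying sample.

    The two experiments share the peptide skeleton (same peptides, proteins,
    copy numbers, implants) but the high-input run uses ``high_input_scale``
    and, when ``high_score_seed`` is given, independent score noise --
    emulating a separate acquisition of a larger aliquot of the same material.
    """
    low = simulate_experiment(config, proteome, abundance)
    high_cfg = config.model_copy(
        update={"input_scale": high_input_scale, "sample": config.sample + "_high"}
    )
    high = simulate_experiment(high_cfg, proteome, abundance, score_seed=high_score_seed)
    return low, high


def apply_denovo_noise(peptides, alc: float, seed: int) -> list[str]:
    """Substitution channel emulating de novo sequencing errors.

    Each residue is independently replaced by one of the 19 alternative
    residues with probability ``(100 - alc) / 200``: full confidence
    (``alc=100``) reproduces the input exactly, and lower confidence degrades
    it linearly. Lengths are preserved (no indels).
    """
    if not 0.0 <= alc <= 100.0:
        raise InvalidArgumentError(f"alc must lie in [0, 100], got {alc}")
    peptides = list(peptides)
    p = (100.0 - alc) / 200.0
    if p == 0.0 or not peptides:
        return peptides
    rng = substream(seed, "noise")
    lengths = [len(s) for s in peptides]
    codes = encode("".join(peptides))
    mask = rng.random(codes.size) < p
    shift = rng.integers(1, N_RESIDUES, size=int(mask.sum()))
    codes[mask] = (codes[mask] + shift) % N_RESIDUES
    out = []
    pos = 0
    for ln in lengths:
        out.append(decode(codes[pos : pos + ln]))
        pos += ln
    return out
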