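"""Source-protein abundance-rank coverage of an immunopeptidome.

Given a quantitative proteome (accession + replicate abundance columns) and
the source proteins of accepted HLA peptides, this module ranks proteins by
mean abundance, marks which ranked proteins contributed at least one peptide
(the "barcode"), and summarises the enrichment of high-abundance source
proteins as a cumulative coverage curve: walking from the most to the least
abundant protein, the running count of immunopeptidome hits as a percentage
of all hits. Under abundance-indifferent sampling the curve is the diagonal;
preference for abundant source proteins bends it upward, quantified by the
percentage of top-ranked proteins needed to reach 50% of hits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedStatisticError

__all__ = [
    "strip_accession",
    "rank_proteome",
    "barcode",
    "cumulative_curve",
    "coverage_stats",
    "AbundanceRanking",
    "abundance_ranking",
]

logger = logging.getLogger(__name__)

_DB_PREFIX = re.compile(r"^(?:sp|tr)\|([^|]+)\|?.*$")


def strip_accession(accession: str) -> str:
    """Strip UniProt-style database prefixes: ``sp|P12345|NAME`` -> ``P12345``."""
    m = _DB_PREFIX.match(accession)
    return m.group(1) if m else accession


def rank_proteome(abundance_table: pd.DataFrame) -> pd.DataFrame:
    """Rank proteins by mean abundance, descending.

    The first column is taken as the accession; every remaining numeric
    column is a replicate measurement, averaged per protein. Duplicate
    accessions are aggregated by mean (with a logged notice). Ties are broken
    by lexicographic accession order, making the ranking deterministic.
    """
    if abundance_table.shape[1] < 2:
        raise InvalidArgumentError("abundance table needs an accession and >= 1 value column")
    acc_col = abundance_table.columns[0]
    values = abundance_table.drop(columns=[acc_col]).apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise InvalidArgumentError("non-numeric abundance value(s) in table")
    df = pd.DataFrame(
        {
            "accession": abundance_table[acc_col].astype(str).map(strip_accession),
            "mean_abundance": values.mean(axis=1),
        }
    )
    if df["accession"].duplicated().any():
        n_dup = int(df["accession"].duplicated().sum())
        logger.info("aggregating %d duplicate accession(s) by mean", n_dup)
        df = df.groupby("accession", as_index=False)["mean_abundance"].mean()
    df = df.sort_values(
        ["mean_abundance", "accession"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.index.name = "rank"
    return df


def barcode(ranked_accessions, source_accessions) -> tuple[np.ndarray, set[str]]:
    """Binary hit flags along the ranked proteome.

    ``flags[r] = 1`` iff ranked protein ``r`` contributed >= 1 peptide;
    source accessions absent from the ranked list are returned separately as
    ``unmapped``. Accessions are compared after prefix stripping.
    """
    ranked = [strip_accession(str(a)) for a in ranked_accessions]
    sources = {strip_accession(str(a)) for a in source_accessions if str(a)}
    ranked_set = set(ranked)
    flags = np.fromiter((1 if a in sources else 0 for a in ranked), dtype=np.int8, count=len(ranked))
    unmapped = sources - ranked_set
    return flags, unmapped


def cumulative_curve(hit_flags: np.ndarray) -> tuple[np.ndarray, float]:
    """Cumulative hit percentage along the ranking, and the half-coverage rank.

    ``cumulative_pct[r]`` is the percentage of all hits found among the top
    ``r+1`` ranked proteins; the half-coverage statistic is the percentage of
    top-ranked proteins needed to accumulate >= 50% of hits.
    """
    flags = np.asarray(hit_flags)
    total = int(flags.sum())
    if total == 0:
        raise UndefinedStatisticError("cumulative curve undefined with zero hits")
    cum = 100.0 * np.cumsum(flags) / total
    r_star = int(np.argmax(cum >= 50.0)) + 1
    half_coverage_rank_pct = 100.0 * r_star / flags.size
    return cum, half_coverage_rank_pct


def coverage_stats(hit_flags: np.ndarray, unmapped_count: int, n_sources: int) -> dict:
    """Proteome coverage and mapped-source percentages.

    ``proteome_coverage_pct``: percentage of ranked proteins hit by >= 1
    peptide; ``mapped_pct``: percentage of immunopeptidome source proteins
    found in the ranked proteome at all.
    """
    if n_sources < 1:
        raise UndefinedStatisticError("coverage statistics undefined without source proteins")
    flags = np.asarray(hit_flags)
    return {
        "proteome_coverage_pct": 100.0 * float(flags.sum()) / flags.size,
        "mapped_pct": 100.0 * (n_sources - unmapped_count) / n_sources,
        "n_ranked": int(flags.size),
        "n_hits": int(flags.sum()),
        "n_sources": int(n_sources),
        "n_unmapped": int(unmapped_count),
    }


@dataclass
class AbundanceRanking:
    """Bundle of the ranked table, barcode, curve and summary statistics."""

    ranked: pd.DataFrame
    hit_flags: np.ndarray
    cumulative_pct: np.ndarray
    half_coverage_rank_pct: float
    stats: dict


def abundance_ranking(abundance_table: pd.DataFrame, source_accessions) -> AbundanceRanking:
    """End-to-end ranking analysis: rank, barcode, curve, coverage stats."""
    ranked = rank_proteome(abundance_table)
    sources = [str(a) for a in source_accessions if str(a)]
    flags, unmapped = barcode(ranked["accession"], sources)
    unique_sources = {strip_accession(a) for a in sources}
    cum, half = cumulative_curve(flags)
    stats = coverage_stats(flags, len(unmapped), len(unique_sources))
    stats["half_coverage_rank_pct"] = half
    return AbundanceRanking(ranked, flags, cum, half, stats)
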