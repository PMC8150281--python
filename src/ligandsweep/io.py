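"""File formats: FASTA via Biopython, TSV tables, allele-profile directories.

All tables are tab-separated UTF-8 with header rows and '.' decimal
separators; peptide sequences are stored uppercase with I and L kept
distinct. Column orders are fixed so that outputs round-trip byte-identically.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS
from .binding import AlleleProfile
from .errors import ConfigurationError

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_table",
    "read_table",
    "read_peptides",
    "write_profiles",
    "read_profiles",
]

PSM_COLUMNS = ["peptide", "score", "is_decoy", "protein", "sample"]
TRUTH_COLUMNS = [
    "peptide",
    "sample",
    "is_true",
    "is_binder",
    "binder_allele",
    "source_protein",
    "copy_number",
]


def write_fasta(proteome: pd.DataFrame, path) -> None:
    records = [
        SeqRecord(Seq(row.sequence), id=row.accession, description="")
        for row in proteome.itertuples()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> pd.DataFrame:
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return pd.DataFrame(rows, columns=["accession", "sequence"])


def write_table(df: pd.DataFrame, path, columns=None) -> None:
    if columns is not None:
        df = df.loc[:, list(columns)]
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"peptide": str, "protein": str, "sample": str},
        float_precision="round_trip",
    )


def read_peptides(path) -> list[str]:
    """Read a peptide list: a TSV with a ``peptide`` column (header required)."""
    df = read_table(path)
    if "peptide" not in df.columns:
        raise ConfigurationError(f"{path}: expected a 'peptide' column")
    return [str(p).upper() for p in df["peptide"]]


def _safe_name(allele: str) -> str:
    return re.sub(r"[^A-Za-z0-9]", "", allele)


def write_profiles(profiles, directory) -> None:
    """Write allele profiles: per allele a PSSM TSV (one section per length)
    and one background-score file per length (one float per line)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for prof in profiles:
        stem = _safe_name(prof.allele)
        with open(directory / f"{stem}.pssm.tsv", "w") as fh:
            fh.write(f"# allele\t{prof.allele}\n")
            for ln in sorted(prof.pssm_by_length):
                smin, smax = prof.score_range_by_length[ln]
                fh.write(f"# length\t{ln}\t{smin!r}\t{smax!r}\n")
                fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\n")
                for pos, row in enumerate(prof.pssm_by_length[ln], start=1):
                    fh.write(str(pos) + "\t" + "\t".join(repr(float(w)) for w in row) + "\n")
        for ln in sorted(prof.background_by_length):
            with open(directory / f"{stem}.bg{ln}.txt", "w") as fh:
                for s in prof.background_by_length[ln]:
                    fh.write(f"{float(s)!r}\n")


def read_profiles(directory) -> list[AlleleProfile]:
    directory = Path(directory)
    profiles = []
    for pssm_path in sorted(directory.glob("*.pssm.tsv")):
        stem = pssm_path.name[: -len(".pssm.tsv")]
        allele = stem
        pssms: dict[int, np.ndarray] = {}
        ranges: dict[int, tuple[float, float]] = {}
        current: list[list[float]] = []
        current_len = None
        with open(pssm_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("# allele"):
                    allele = line.split("\t")[1]
                elif line.startswith("# length"):
                    if current_len is not None:
                        pssms[current_len] = np.array(current)
                    parts = line.split("\t")
                    current_len = int(parts[1])
                    ranges[current_len] = (float(parts[2]), float(parts[3]))
                    current = []
                elif line.startswith("position"):
                    continue
                else:
                    current.append([float(x) for x in line.split("\t")[1:]])
        if current_len is not None:
            pssms[current_len] = np.array(current)
        backgrounds = {}
        for bg_path in sorted(directory.glob(f"{stem}.bg*.txt")):
            ln = int(re.search(r"\.bg(\d+)\.txt$", bg_path.name).group(1))
            backgrounds[ln] = np.loadtxt(bg_path, dtype=float)
        if not pssms or set(pssms) != set(backgrounds):
            raise ConfigurationError(f"incomplete profile files for {allele!r} in {directory}")
        profiles.append(AlleleProfile(allele, pssms, backgrounds, ranges))
    return profiles
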