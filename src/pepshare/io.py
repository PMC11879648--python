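"""Reading and writing feature tables, FASTA databases, and summaries.

The canonical in-memory representation of feature-level data is a long-format
:class:`pandas.DataFrame` with one row per (feature, mixture, channel)
observation and the columns

``protein``
    semicolon-joined, sorted accessions of all proteins the peptide matches
    (the membership set V(f)),
``peptide``
    amino-acid sequence (possibly with modification annotations),
``feature_id``
    peptide-ion identifier (sequence + charge),
``mixture``, ``channel``, ``condition``, ``bio_replicate``
    experimental design labels, and
``log2_intensity``
    the observed log2 reporter intensity; ``NaN`` when the raw intensity was
    absent or non-positive.

Input tables follow the MSstatsTMT column convention (ProteinName,
PeptideSequence, Charge, Mixture, Channel, Condition, BioReplicate,
Intensity); a ``dialect`` mapping can adapt other headers.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical internal column names
FEATURE_COLUMNS = [
    "protein",
    "peptide",
    "feature_id",
    "mixture",
    "channel",
    "condition",
    "bio_replicate",
    "log2_intensity",
]

#: MSstatsTMT-style input header -> canonical name
DEFAULT_DIALECT: Mapping[str, str] = {
    "ProteinName": "protein",
    "PeptideSequence": "peptide",
    "Charge": "charge",
    "PSM": "psm",
    "Mixture": "mixture",
    "Run": "run",
    "Channel": "channel",
    "Condition": "condition",
    "BioReplicate": "bio_replicate",
    "Intensity": "intensity",
}

_REQUIRED = ["protein", "peptide", "channel", "condition", "bio_replicate", "intensity"]


class FormatError(ValueError):
    """Raised when an input table does not conform to the expected format."""


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_feature_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
    protein_delimiter: str = ";",
) -> pd.DataFrame:
    """Read a delimited feature-level quantification table.

    Raw intensities are log2-transformed; rows whose intensity is missing,
    zero or negative are retained with ``log2_intensity = NaN`` (log2 is
    undefined for them and the model simply ignores those cells).

    Parameters
    ----------
    path
        Delimited text file with a header (CSV by default, TSV for
        ``.tsv``/``.txt`` extensions unless ``sep`` overrides).
    dialect
        Mapping from the file's column names to canonical names; merged over
        the MSstatsTMT defaults.
    protein_delimiter
        Separator of multiple accessions inside the protein column.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    raw = pd.read_csv(path, sep=_sep_for(path, sep))
    if raw.empty:
        raise FormatError(f"empty feature table: {path}")
    raw = raw.rename(columns=colmap)
    # already-canonical tables (e.g. written by `annotate`) carry log2 values
    has_log2 = "log2_intensity" in raw.columns and "intensity" not in raw.columns
    required = [c for c in _REQUIRED if not (has_log2 and c == "intensity")]
    for col in required:
        if col not in raw.columns:
            wanted = [k for k, v in colmap.items() if v == col]
            raise FormatError(
                f"missing required column {col!r} (accepted header names: {wanted})"
            )
    out = pd.DataFrame(
        {
            "protein": [
                protein_delimiter.join(sorted(str(p).split(protein_delimiter)))
                for p in raw["protein"]
            ],
            "peptide": raw["peptide"].astype(str),
        }
    )
    if "feature_id" in raw.columns:
        out["feature_id"] = raw["feature_id"].astype(str)
    elif "psm" in raw.columns:
        out["feature_id"] = raw["psm"].astype(str)
    elif "charge" in raw.columns:
        out["feature_id"] = raw["peptide"].astype(str) + "_" + raw["charge"].astype(str)
    else:
        out["feature_id"] = raw["peptide"].astype(str)
    out["mixture"] = raw["mixture"].astype(str) if "mixture" in raw.columns else "1"
    out["channel"] = raw["channel"].astype(str)
    out["condition"] = raw["condition"].astype(str)
    out["bio_replicate"] = raw["bio_replicate"].astype(str)
    if has_log2:
        out["log2_intensity"] = pd.to_numeric(raw["log2_intensity"], errors="coerce")
    else:
        intensity = pd.to_numeric(raw["intensity"], errors="coerce").to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2 = np.where(
                intensity > 0, np.log2(np.where(intensity > 0, intensity, 1.0)), np.nan
            )
        out["log2_intensity"] = log2
    return out.reset_index(drop=True)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA database as a mapping accession -> sequence.

    The accession is the first whitespace-delimited token of the record id;
    UniProt-style ``db|ACC|NAME`` ids are reduced to ``ACC``.
    """
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split()[0]
        parts = acc.split("|")
        if len(parts) >= 3:
            acc = parts[1]
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {acc} in {path}")
        entries[acc] = seq
    return entries


_MOD_PATTERN = re.compile(r"\[[^\]]*\]|\([^)]*\)|[^A-Za-z]")


def strip_modifications(peptide: str) -> str:
    """Reduce a (possibly modified) peptide string to its plain sequence.

    Bracketed or parenthesised modification annotations and non-letter
    characters are removed; the result is upper-cased for database matching.
    """
    return _MOD_PATTERN.sub("", peptide).upper()


def annotate_peptides(
    features: pd.DataFrame,
    db: Mapping[str, str],
    protein_delimiter: str = ";",
) -> pd.DataFrame:
    """Re-annotate peptide->protein membership against a sequence database.

    Each feature's protein labels are replaced by the full set of accessions
    whose sequence contains the (modification-stripped) peptide sequence as a
    contiguous substring. Features matching no database protein are dropped;
    the count of dropped features is logged.
    """
    if not db:
        raise ValueError("sequence database is empty")
    accessions = sorted(db)
    match_cache: dict[str, str] = {}

    def _labels(peptide: str) -> str:
        plain = strip_modifications(peptide)
        if plain not in match_cache:
            hits = [acc for acc in accessions if plain in db[acc]]
            match_cache[plain] = protein_delimiter.join(hits)
        return match_cache[plain]

    labels = features["peptide"].map(_labels)
    keep = labels != ""
    n_dropped = int(features.loc[~keep, "feature_id"].nunique())
    if n_dropped:
        logger.info("annotate_peptides: dropped %d features matching no protein", n_dropped)
    out = features.loc[keep].copy()
    out["protein"] = labels[keep]
    return out.reset_index(drop=True)


def normalize_to_reference_channel(
    features: pd.DataFrame, reference_channel: str
) -> pd.DataFrame:
    """Optional between-mixture centering against a reference channel.

    Within each mixture, subtracts the difference between that mixture's
    median log2 intensity in the reference channel and the overall median of
    the reference channel, aligning mixtures on their reference material.
    Off by default everywhere; summarization does not normalize.
    """
    ref = features[features["channel"].astype(str) == str(reference_channel)]
    if ref.empty:
        raise ValueError(f"reference channel {reference_channel!r} not present")
    overall = ref["log2_intensity"].median()
    per_mixture = ref.groupby(ref["mixture"].astype(str))["log2_intensity"].median()
    out = features.copy()
    shift = out["mixture"].astype(str).map(per_mixture - overall)
    out["log2_intensity"] = out["log2_intensity"] - shift
    return out


SUMMARY_COLUMNS = ["protein", "mixture", "channel", "condition", "bio_replicate", "summary"]


def write_summaries(
    summaries: pd.DataFrame,
    path: str | Path,
    weights: pd.DataFrame | None = None,
    convergence: pd.DataFrame | None = None,
) -> None:
    """Write protein-level summaries, with optional companion tables.

    The main file has one row per (protein, mixture, channel) with the design
    metadata and the log2 summary. Weights go to ``<stem>_weights.tsv`` and
    per-cluster convergence records to ``<stem>_convergence.tsv``.
    """
    path = Path(path)
    cols = [c for c in SUMMARY_COLUMNS if c in summaries.columns]
    summaries.loc[:, cols].to_csv(path, sep="\t", index=False)
    if weights is not None:
        weights.to_csv(path.with_name(path.stem + "_weights.tsv"), sep="\t", index=False)
    if convergence is not None:
        convergence.to_csv(path.with_name(path.stem + "_convergence.tsv"), sep="\t", index=False)


def read_summaries(path: str | Path) -> pd.DataFrame:
    """Read back a summary table written by :func:`write_summaries`."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in SUMMARY_COLUMNS[:-1]})
    df["summary"] = pd.to_numeric(df["summary"], errors="coerce")
    return df
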