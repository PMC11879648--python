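"""PTM-site summarization and protein-adjusted differential occupancy.

Modification sites play the role of proteins in the weighted cluster model:
a peptide modified at a single site is a unique feature of that site, while
a multiply-modified peptide is shared across all its sites. Site clusters
never span proteins. After summarization and per-site differential testing,
changes in site occupancy are adjusted for changes of the unmodified
protein by differencing the log2 fold changes.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_SITE_RE = re.compile(r"^[A-Z]\d+$")

#: separator between protein accession and site label in the site unit id
SITE_SEP = ":"


def site_label(protein: str, site: str) -> str:
    """Quantified-unit label of one site of one protein, e.g. ``P1:S236``."""
    return f"{protein}{SITE_SEP}{site}"


def expand_sites(
    features: pd.DataFrame,
    annotations: pd.DataFrame,
    site_delimiter: str = ";",
) -> pd.DataFrame:
    """Rewrite a feature table so each PTM site is a quantified unit.

    ``annotations`` has columns ``feature_id``, ``protein`` and ``sites``
    (delimiter-joined residue+position labels such as ``S236``, 1-based
    protein coordinates). The returned table's protein column holds the
    protein-scoped site set of each feature, so singly-modified peptides are
    unique features of their site and multiply-modified peptides are shared
    across their sites; no concatenated multi-site labels are created.
    Features without an annotation are dropped and counted in the log.
    """
    ann: dict[str, str] = {}
    for _, row in annotations.iterrows():
        sites = [s.strip() for s in str(row["sites"]).split(site_delimiter) if s.strip()]
        if not sites:
            raise ValueError(f"empty site list for feature {row['feature_id']}")
        for s in sites:
            if not _SITE_RE.match(s):
                raise ValueError(f"malformed site label {s!r} (expect e.g. 'S236')")
        ann[str(row["feature_id"])] = site_delimiter.join(
            sorted(site_label(str(row["protein"]), s) for s in set(sites))
        )
    keep = features["feature_id"].astype(str).isin(ann)
    n_dropped = int(features.loc[~keep, "feature_id"].nunique())
    if n_dropped:
        logger.info("expand_sites: dropped %d unannotated features", n_dropped)
    out = features.loc[keep].copy()
    out["protein"] = out["feature_id"].astype(str).map(ann)
    return out.reset_index(drop=True)


def adjusted_test(ptm_result: dict | pd.Series, protein_result: dict | pd.Series | None) -> dict:
    """Adjust a PTM-site differential result for protein-level change.

    The null hypothesis compares the change in site abundance to the change
    of the unmodified protein: the adjusted estimate is the difference of
    log2 fold changes, its standard error combines the two in quadrature,
    and the degrees of freedom follow the Satterthwaite approximation

        df = (se_ptm^2 + se_prot^2)^2 / (se_ptm^4/df_ptm + se_prot^4/df_prot).

    A missing protein result returns the unadjusted record, flagged.
    """
    ptm = dict(ptm_result)
    if protein_result is None:
        out = dict(ptm)
        out["adjusted"] = False
        logger.warning("no protein result for %s; returning unadjusted", ptm.get("protein"))
        return out
    prot = dict(protein_result)
    fc = float(ptm["log2fc"]) - float(prot["log2fc"])
    v1, v2 = float(ptm["se"]) ** 2, float(prot["se"]) ** 2
    se = float(np.sqrt(v1 + v2))
    if v1 + v2 == 0.0:
        df = float(ptm["df"])
        p = 0.0 if fc != 0 else 1.0
    else:
        denom = 0.0
        if v1 > 0:
            denom += v1 ** 2 / float(ptm["df"])
        if v2 > 0:
            denom += v2 ** 2 / float(prot["df"])
        df = (v1 + v2) ** 2 / denom
        p = float(2.0 * sps.t.sf(abs(fc / se), df))
    return {
        "protein": ptm.get("protein"),
        "contrast": ptm.get("contrast"),
        "log2fc": fc,
        "se": se,
        "df": df,
        "p_value": p,
        "protein_log2fc": float(prot["log2fc"]),
        "adjusted": True,
    }


def adjust_results(
    ptm_results: pd.DataFrame, protein_results: pd.DataFrame
) -> pd.DataFrame:
    """Adjust a table of per-site results by the matching protein results.

    Site units are matched to proteins by the accession before the
    ``protein:site`` separator; matching is on (accession, contrast).
    """
    prot_lookup = {
        (str(r["protein"]), str(r["contrast"])): r
        for _, r in protein_results.iterrows()
    }
    rows = []
    for _, r in ptm_results.iterrows():
        acc = str(r["protein"]).split(SITE_SEP)[0]
        match = prot_lookup.get((acc, str(r["contrast"])))
        rows.append(adjusted_test(r, match))
    return pd.DataFrame(rows)
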