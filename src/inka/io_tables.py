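"""Readers for MaxQuant-dialect phosphopeptide and phosphosite tables.

Quantified phosphopeptides come from a ``modificationSpecificPeptides``-like
table and localized phosphosites from a ``Phospho (STY)Sites``-like table,
both tab-separated with a header row.  Column headers differ between MaxQuant
versions, so every logical field is resolved through a column map that the
caller can override (logical field name -> header string).

The two tables are merged into a single non-redundant class-I
phosphosite-phosphopeptide table, the input to all downstream scoring:

``gene_symbol, peptide_sequence, n_phospho, accession, position, residue,
localization_probability, n_inferred_sites, <one quant column per sample>``

Positions are 1-based residue indices on the protein; peptide sequences are
plain amino-acid strings without modification markup.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError

logger = logging.getLogger(__name__)

#: Class-I localization-probability threshold (strict: kept iff prob > 0.75).
CLASS_I_THRESHOLD = 0.75

#: Default logical-field -> header map for the phosphopeptide table.
DEFAULT_PEPTIDE_COLUMNS: dict[str, str] = {
    "peptide_sequence": "Sequence",
    "gene_symbol": "Gene Names",
    "n_phospho": "Phospho (STY)",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}

#: Default logical-field -> header map for the phosphosite table.
DEFAULT_SITE_COLUMNS: dict[str, str] = {
    "accession": "Protein",
    "gene_symbol": "Gene names",
    "position": "Position",
    "residue": "Amino acid",
    "localization_probability": "Localization prob",
    "peptide_sequence": "Peptide sequence",
}

VALID_RESIDUES = frozenset("STY")

MERGED_KEY = ["gene_symbol", "position", "residue", "peptide_sequence", "n_phospho"]
_MERGED_BASE = [
    "gene_symbol",
    "peptide_sequence",
    "n_phospho",
    "accession",
    "position",
    "residue",
    "localization_probability",
    "n_inferred_sites",
]


def _require_columns(frame: pd.DataFrame, headers: Sequence[str]) -> None:
    missing = [h for h in headers if h not in frame.columns]
    if missing:
        raise InputFormatError(f"missing required column(s): {missing}")


def _to_numeric(series: pd.Series, name: str) -> pd.Series:
    """Parse a string column to float; an unparsable non-empty cell is fatal."""
    stripped = series.astype("string").str.strip()
    out = pd.to_numeric(stripped, errors="coerce")
    bad = stripped.notna() & (stripped != "") & out.isna()
    if bad.any():
        row = int(series.index[bad][0])
        raise InputFormatError(
            f"unparsable numeric value {series[bad].iloc[0]!r} in column "
            f"{name!r} at row {row}"
        )
    return out.astype(float)


def read_phosphopeptide_table(
    path,
    sample_ids: Sequence[str],
    quant_mode: str = "counts",
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and deconvolute a quantified phosphopeptide table ("table 1").

    One output row per (input row x gene symbol): rows whose gene field lists
    several semicolon-separated symbols are split into one row per symbol.
    Decoy/contaminant-flagged rows (when those columns exist) and rows with
    zero phospho modifications are dropped.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    return process_peptide_frame(raw, sample_ids, quant_mode=quant_mode, columns=columns)


def process_peptide_frame(
    raw: pd.DataFrame,
    sample_ids: Sequence[str],
    quant_mode: str = "counts",
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Apply phosphopeptide-table processing to an already-parsed frame."""
    if quant_mode not in ("counts", "intensity"):
        raise ValueError(f"unknown quant_mode {quant_mode!r}")
    sample_ids = list(sample_ids)
    cols = {**DEFAULT_PEPTIDE_COLUMNS, **(columns or {})}
    raw = raw.reset_index(drop=True)
    _require_columns(
        raw, [cols["peptide_sequence"], cols["gene_symbol"], cols["n_phospho"], *sample_ids]
    )

    out = pd.DataFrame(
        {
            "peptide_sequence": raw[cols["peptide_sequence"]].astype("string").str.strip(),
            "gene_symbol": raw[cols["gene_symbol"]].astype("string").fillna(""),
            "n_phospho": _to_numeric(raw[cols["n_phospho"]], cols["n_phospho"]),
        }
    )
    for sid in sample_ids:
        quant = _to_numeric(raw[sid], sid).fillna(0.0)
        if (quant < 0).any():
            raise InputFormatError(f"negative quantification value in column {sid!r}")
        out[sid] = quant

    # decoy / contaminant flags are optional; a "+" marks a row to drop
    keep = pd.Series(True, index=out.index)
    for flag in ("reverse", "contaminant"):
        header = cols.get(flag)
        if header and header in raw.columns:
            flagged = raw[header].astype("string").fillna("").str.strip() == "+"
            if flagged.any():
                logger.info("dropping %d %s-flagged peptide rows", int(flagged.sum()), flag)
            keep &= ~flagged
    out = out[keep]

    nonphospho = out["n_phospho"].isna() | (out["n_phospho"] < 1)
    if nonphospho.any():
        logger.info("dropping %d rows without phospho modifications", int(nonphospho.sum()))
    out = out[~nonphospho]
    out["n_phospho"] = out["n_phospho"].astype(int)

    # deconvolute multi-gene rows into one row per gene symbol
    out = out.assign(gene_symbol=out["gene_symbol"].str.split(";")).explode("gene_symbol")
    out["gene_symbol"] = out["gene_symbol"].astype("string").str.strip()
    empty = (out["gene_symbol"] == "") | out["gene_symbol"].isna()
    if empty.any():
        logger.info("dropping %d rows without a gene symbol", int(empty.sum()))
    out = out[~empty]
    out["gene_symbol"] = out["gene_symbol"].astype(str)
    out["peptide_sequence"] = out["peptide_sequence"].astype(str)

    # collapse duplicate (peptide, gene, n_phospho) rows by summing quant
    key = ["peptide_sequence", "gene_symbol", "n_phospho"]
    if out.duplicated(key).any():
        logger.info(
            "summing quantification over %d duplicate peptide rows",
            int(out.duplicated(key).sum()),
        )
        out = out.groupby(key, as_index=False)[sample_ids].sum()
    return out.reset_index(drop=True)[key + sample_ids]


def _split_parallel(frame: pd.DataFrame, fields: Sequence[str]) -> pd.DataFrame:
    """Explode semicolon-separated parallel list fields, broadcasting singletons."""
    parts = {f: frame[f].astype("string").fillna("").str.split(";") for f in fields}
    lengths = pd.DataFrame({f: p.str.len() for f, p in parts.items()})
    width = lengths.max(axis=1)
    rows = []
    for i in frame.index:
        n = int(width[i])
        vals = {}
        for f in fields:
            lst = [v.strip() for v in parts[f][i]]
            if len(lst) == 1:
                lst = lst * n
            elif len(lst) != n:
                raise InputFormatError(
                    f"mismatched multi-value fields at row {i}: "
                    f"{f!r} has {len(lst)} entries, expected {n}"
                )
            vals[f] = lst
        base = frame.loc[i].drop(list(fields))
        for j in range(n):
            rows.append({**base.to_dict(), **{f: vals[f][j] for f in fields}})
    return pd.DataFrame(rows)


def read_phosphosite_table(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a phosphosite table and keep class-I sites only ("table 2").

    Rows linking one site to multiple accessions or peptides are split into
    separate records; only sites with localization probability strictly above
    0.75 survive.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    return process_site_frame(raw, columns=columns)


def process_site_frame(raw: pd.DataFrame, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Apply phosphosite-table processing to an already-parsed frame."""
    cols = {**DEFAULT_SITE_COLUMNS, **(columns or {})}
    raw = raw.reset_index(drop=True)
    _require_columns(raw, [cols[f] for f in DEFAULT_SITE_COLUMNS])

    out = pd.DataFrame(
        {
            "accession": raw[cols["accession"]],
            "gene_symbol": raw[cols["gene_symbol"]],
            "position": raw[cols["position"]],
            "residue": raw[cols["residue"]].astype("string").str.strip(),
            "localization_probability": _to_numeric(
                raw[cols["localization_probability"]], cols["localization_probability"]
            ),
            "peptide_sequence": raw[cols["peptide_sequence"]],
        }
    )
    prob = out["localization_probability"]
    if ((prob < 0) | (prob > 1)).any():
        raise InputFormatError("localization probability outside [0, 1]")

    n_before = len(out)
    out = out[prob > CLASS_I_THRESHOLD]
    logger.info("class-I filter kept %d of %d site rows", len(out), n_before)
    if out.empty:
        return pd.DataFrame(
            columns=[
                "accession",
                "gene_symbol",
                "position",
                "residue",
                "localization_probability",
                "peptide_sequence",
            ]
        )

    # deconvolute parallel accession/gene/position lists, then peptide lists
    out = _split_parallel(out, ["accession", "gene_symbol", "position"])
    out = out.assign(
        peptide_sequence=out["peptide_sequence"].astype("string").fillna("").str.split(";")
    ).explode("peptide_sequence")
    out["peptide_sequence"] = out["peptide_sequence"].astype("string").str.strip()
    out = out[(out["peptide_sequence"] != "") & (out["gene_symbol"] != "")]

    out["position"] = _to_numeric(out["position"].astype("string"), "position")
    if (out["position"] < 1).any() or out["position"].isna().any():
        raise InputFormatError("site positions must be 1-based positive integers")
    out["position"] = out["position"].astype(int)
    badres = ~out["residue"].isin(VALID_RESIDUES)
    if badres.any():
        raise InputFormatError(
            f"unexpected phosphoacceptor residue {out['residue'][badres].iloc[0]!r}"
        )
    for col in ("accession", "gene_symbol", "residue", "peptide_sequence"):
        out[col] = out[col].astype(str)
    return out.drop_duplicates().reset_index(drop=True)


def merge_site_peptide(
    peptides: pd.DataFrame,
    sites: pd.DataFrame,
    accession_priority: Mapping[str, int] | None = None,
    symbol_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Merge tables 1 and 2 into the non-redundant class-I site-peptide table.

    Join is on (gene_symbol, peptide_sequence).  For each (site, gene)
    combination exactly one accession is retained: the lowest value in
    ``accession_priority`` wins (missing -> lowest priority), ties break to the
    lexicographically smallest accession.  Rows made redundant by symbol
    mapping (same official symbol, same peptide, same site) collapse to one.
    Unmatched rows on either side are dropped and counted in the log.
    """
    peptides = peptides.copy()
    sites = sites.copy()
    sample_ids = [c for c in peptides.columns if c not in ("peptide_sequence", "gene_symbol", "n_phospho")]

    if symbol_map:
        from .knowledgebases import map_symbols

        peptides["gene_symbol"] = map_symbols(peptides["gene_symbol"], symbol_map)
        sites["gene_symbol"] = map_symbols(sites["gene_symbol"], symbol_map)
        # re-collapse peptides whose symbols merged under mapping
        key = ["peptide_sequence", "gene_symbol", "n_phospho"]
        peptides = peptides.groupby(key, as_index=False)[sample_ids].max()

    merged = sites.merge(peptides, on=["gene_symbol", "peptide_sequence"], how="inner")
    n_sites_dropped = len(
        sites.merge(peptides[["gene_symbol", "peptide_sequence"]].drop_duplicates(),
                    on=["gene_symbol", "peptide_sequence"], how="left", indicator=True)
        .query("_merge == 'left_only'")
    )
    matched_peps = merged[["gene_symbol", "peptide_sequence"]].drop_duplicates()
    n_peps_dropped = len(peptides) - len(
        peptides.merge(matched_peps, on=["gene_symbol", "peptide_sequence"])
    )
    if n_sites_dropped or n_peps_dropped:
        logger.info(
            "merge dropped %d unmatched site rows and %d unmatched peptide rows",
            n_sites_dropped,
            n_peps_dropped,
        )
    if merged.empty:
        return pd.DataFrame(columns=_MERGED_BASE + sample_ids)

    # one best-annotated accession per (gene, position, residue) combination
    prio = accession_priority or {}
    merged["_prio"] = merged["accession"].map(lambda a: prio.get(a, np.inf))
    best = (
        merged.sort_values(["_prio", "accession"], kind="mergesort")
        .groupby(["gene_symbol", "position", "residue"], sort=False)["accession"]
        .first()
        .rename("_best")
    )
    merged = merged.join(best, on=["gene_symbol", "position", "residue"])
    merged = merged[merged["accession"] == merged["_best"]].drop(columns=["_prio", "_best"])

    # collapse residual redundancy (same official symbol, site, peptide)
    merged = merged.drop_duplicates(MERGED_KEY)

    # number of distinct class-I sites inferred for each (gene, peptide)
    n_inferred = (
        merged.groupby(["gene_symbol", "peptide_sequence"])["position"]
        .transform("nunique")
        .astype(int)
    )
    merged["n_inferred_sites"] = n_inferred
    merged = merged.sort_values(MERGED_KEY, kind="mergesort").reset_index(drop=True)
    return merged[_MERGED_BASE + sample_ids]


def write_merged_table(merged: pd.DataFrame, path) -> None:
    """Serialize the merged site-peptide table as tab-separated text."""
    merged.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_merged_table(path) -> pd.DataFrame:
    """Read back a merged table written by :func:`write_merged_table`."""
    out = pd.read_csv(path, sep="\t")
    for col in ("gene_symbol", "peptide_sequence", "accession", "residue"):
        out[col] = out[col].astype(str)
    return out
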