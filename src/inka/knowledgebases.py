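"""Annotation resources backing kinase-activity inference.

Five resources are consumed, all as plain tab-separated text:

* curated kinase-substrate relations (PhosphoSitePlus
  ``Kinase_Substrate_Dataset`` dialect),
* predicted kinase-substrate relations (NetworKIN output dialect, filtered on
  the prediction score),
* kinase activation-loop tryptic peptides (Phomics-style gene/peptide list),
* the catalog of established protein-kinase gene symbols (KinBase-style,
  one symbol per line),
* an official gene-symbol map (HGNC-style two-column old -> official).

Relations from both sources are normalized to a single frame with columns
``kinase_symbol, substrate_symbol, position, residue, source,
prediction_score`` (score present only for predicted relations).
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import InkaError, InputFormatError

logger = logging.getLogger(__name__)

#: Absolute NetworKIN score floor.
NETWORKIN_MIN_SCORE = 2.0
#: Fraction of the per-site maximum a prediction must strictly exceed.
NETWORKIN_RELATIVE_FRACTION = 0.9
#: Predictions carrying this STRING identifier are attributed to LYN.
LYN_STRING_IDENTIFIER = "ENSP00000376688"

RELATION_COLUMNS = [
    "kinase_symbol",
    "substrate_symbol",
    "position",
    "residue",
    "source",
    "prediction_score",
]

DEFAULT_PSP_COLUMNS: dict[str, str] = {
    "kinase_symbol": "GENE",
    "substrate_symbol": "SUB_GENE",
    "site": "SUB_MOD_RSD",
    "kinase_organism": "KIN_ORGANISM",
    "substrate_organism": "SUB_ORGANISM",
}

DEFAULT_NETWORKIN_COLUMNS: dict[str, str] = {
    "substrate_symbol": "substrate_name",
    "position": "position",
    "residue": "residue",
    "kinase_symbol": "id",
    "tree": "tree",
    "score": "networkin_score",
    "string_identifier": "string_identifier",
}

_SITE_RE = re.compile(r"^([STY])(\d+)$")


@dataclass(frozen=True)
class KnowledgeBase:
    """Bundle of loaded annotation resources used throughout scoring."""

    relations: pd.DataFrame
    activation_loops: pd.DataFrame
    kinome: frozenset[str]
    symbol_map: dict[str, str] = field(default_factory=dict)

    def out_of_scope(self) -> frozenset[str]:
        """Catalog kinases absent from both relation sources.

        These can never obtain substrate-centric evidence and are ranked
        separately on kinase-centric evidence alone.
        """
        covered = set(self.relations["kinase_symbol"]) if len(self.relations) else set()
        return frozenset(self.kinome - covered)


def map_symbols(symbols: Iterable[str] | pd.Series, mapping: Mapping[str, str]) -> pd.Series:
    """Normalize gene symbols through an old -> official map.

    Symbols missing from the map pass through unchanged; those that are
    neither keys nor official values trigger one aggregated warning.
    """
    series = pd.Series(symbols, dtype=str) if not isinstance(symbols, pd.Series) else symbols.astype(str)
    if not mapping:
        return series.copy()
    mapped = series.map(mapping).fillna(series)
    official = set(mapping.values())
    unknown = sorted(set(series[~series.isin(mapping) & ~series.isin(official)]))
    if unknown:
        logger.warning("passing through %d unmapped gene symbols: %s", len(unknown), unknown[:10])
    return mapped


def load_symbol_map(path) -> dict[str, str]:
    """Read a two-column (old, official) tab-separated symbol map."""
    frame = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if frame.shape[1] < 2:
        raise InputFormatError("symbol map needs two columns (old, official)")
    old, new = frame.columns[:2]
    return dict(zip(frame[old].str.strip(), frame[new].str.strip()))


def parse_psp_frame(
    raw: pd.DataFrame,
    columns: Mapping[str, str] | None = None,
    symbol_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Normalize a PhosphoSitePlus-dialect kinase-substrate frame."""
    cols = {**DEFAULT_PSP_COLUMNS, **(columns or {})}
    required = [cols["kinase_symbol"], cols["substrate_symbol"], cols["site"]]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise InputFormatError(f"missing required column(s): {missing}")

    frame = raw.copy()
    # keep human-human entries when species columns are present
    for key in ("kinase_organism", "substrate_organism"):
        header = cols.get(key)
        if header and header in frame.columns:
            frame = frame[frame[header].astype(str).str.strip().str.lower() == "human"]

    sites = frame[cols["site"]].astype(str).str.strip().str.upper()
    parsed = sites.str.extract(_SITE_RE)
    bad = parsed[0].isna()
    if bad.any():
        raise InputFormatError(
            f"cannot parse substrate site {sites[bad].iloc[0]!r} (expected e.g. 'Y416')"
        )
    out = pd.DataFrame(
        {
            "kinase_symbol": frame[cols["kinase_symbol"]].astype(str).str.strip().str.upper(),
            "substrate_symbol": frame[cols["substrate_symbol"]].astype(str).str.strip().str.upper(),
            "position": parsed[1].astype(int),
            "residue": parsed[0],
            "source": "PSP",
            "prediction_score": float("nan"),
        }
    )
    if symbol_map:
        out["kinase_symbol"] = map_symbols(out["kinase_symbol"], symbol_map)
        out["substrate_symbol"] = map_symbols(out["substrate_symbol"], symbol_map)
    out = out.drop_duplicates(["kinase_symbol", "substrate_symbol", "position", "residue"])
    return out.reset_index(drop=True)[RELATION_COLUMNS]


def load_psp_relations(
    path,
    columns: Mapping[str, str] | None = None,
    symbol_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load curated kinase-substrate relations (PhosphoSitePlus dialect)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    return parse_psp_frame(raw, columns=columns, symbol_map=symbol_map)


def parse_networkin_frame(
    raw: pd.DataFrame,
    columns: Mapping[str, str] | None = None,
    symbol_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Standardize a NetworKIN-dialect prediction frame (no score filtering)."""
    cols = {**DEFAULT_NETWORKIN_COLUMNS, **(columns or {})}
    required = [cols[k] for k in ("substrate_symbol", "position", "residue", "kinase_symbol", "score")]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise InputFormatError(f"missing required column(s): {missing}")

    frame = raw.copy()
    tree_header = cols.get("tree")
    if tree_header and tree_header in frame.columns:
        frame = frame[frame[tree_header].astype(str).str.strip().str.upper() == "KIN"]

    out = pd.DataFrame(
        {
            "kinase_symbol": frame[cols["kinase_symbol"]].astype(str).str.strip().str.upper(),
            "substrate_symbol": frame[cols["substrate_symbol"]].astype(str).str.strip().str.upper(),
            "position": pd.to_numeric(frame[cols["position"]], errors="raise").astype(int),
            "residue": frame[cols["residue"]].astype(str).str.strip().str.upper(),
            "score": pd.to_numeric(frame[cols["score"]], errors="raise").astype(float),
        }
    )
    sid_header = cols.get("string_identifier")
    if sid_header and sid_header in frame.columns:
        out["string_identifier"] = frame[sid_header].astype(str).str.strip()
    else:
        out["string_identifier"] = ""
    if symbol_map:
        out["kinase_symbol"] = map_symbols(out["kinase_symbol"], symbol_map)
        out["substrate_symbol"] = map_symbols(out["substrate_symbol"], symbol_map)
    return out.reset_index(drop=True)


def filter_networkin(
    predictions: pd.DataFrame,
    min_score: float = NETWORKIN_MIN_SCORE,
    relative_fraction: float = NETWORKIN_RELATIVE_FRACTION,
) -> pd.DataFrame:
    """Apply the prediction-score filter and return normalized relations.

    A prediction is kept iff its score is at least ``min_score`` *and*
    strictly exceeds ``relative_fraction`` of the maximum score among
    predictions for the same substrate site.  The per-site maximum therefore
    always survives whenever it clears the absolute floor.  Predictions whose
    STRING identifier is ENSP00000376688 are attributed to LYN.
    """
    pred = predictions.copy()
    if pred.empty:
        return pd.DataFrame(columns=RELATION_COLUMNS)
    pred.loc[pred["string_identifier"] == LYN_STRING_IDENTIFIER, "kinase_symbol"] = "LYN"

    site_key = ["substrate_symbol", "position", "residue"]
    site_max = pred.groupby(site_key)["score"].transform("max")
    keep = (pred["score"] >= min_score) & (pred["score"] > relative_fraction * site_max)
    kept = pred[keep]

    out = pd.DataFrame(
        {
            "kinase_symbol": kept["kinase_symbol"],
            "substrate_symbol": kept["substrate_symbol"],
            "position": kept["position"],
            "residue": kept["residue"],
            "source": "NWK",
            "prediction_score": kept["score"],
        }
    )
    # set semantics: one relation per (kinase, site), highest score retained
    out = (
        out.sort_values("prediction_score", ascending=False, kind="mergesort")
        .drop_duplicates(["kinase_symbol", "substrate_symbol", "position", "residue"])
        .sort_values(["kinase_symbol", "substrate_symbol", "position", "residue"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out[RELATION_COLUMNS]


def load_networkin_relations(
    path,
    columns: Mapping[str, str] | None = None,
    symbol_map: Mapping[str, str] | None = None,
    min_score: float = NETWORKIN_MIN_SCORE,
    relative_fraction: float = NETWORKIN_RELATIVE_FRACTION,
) -> pd.DataFrame:
    """Load and filter NetworKIN predictions into normalized relations."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    pred = parse_networkin_frame(raw, columns=columns, symbol_map=symbol_map)
    return filter_networkin(pred, min_score=min_score, relative_fraction=relative_fraction)


def combine_relations(*relation_frames: pd.DataFrame) -> pd.DataFrame:
    """Pool relation frames from several sources into one table."""
    frames = [f for f in relation_frames if f is not None and len(f)]
    if not frames:
        return pd.DataFrame(columns=RELATION_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(
        ["kinase_symbol", "substrate_symbol", "position", "residue", "source"]
    ).reset_index(drop=True)


def load_activation_loops(
    path,
    columns: Mapping[str, str] | None = None,
    symbol_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load activation-segment tryptic-peptide annotations (gene, peptide)."""
    cols = {"gene_symbol": "gene_symbol", "peptide_sequence": "peptide_sequence", **(columns or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in (cols["gene_symbol"], cols["peptide_sequence"]) if c not in raw.columns]
    if missing:
        raise InputFormatError(f"missing required column(s): {missing}")
    out = pd.DataFrame(
        {
            "gene_symbol": raw[cols["gene_symbol"]].astype(str).str.strip().str.upper(),
            "peptide_sequence": raw[cols["peptide_sequence"]]
            .astype("string")
            .fillna("")
            .str.strip()
            .astype(str),
        }
    )
    if (out["peptide_sequence"] == "").any():
        raise InputFormatError("empty activation-loop peptide sequence")
    if symbol_map:
        out["gene_symbol"] = map_symbols(out["gene_symbol"], symbol_map)
    return out.drop_duplicates().reset_index(drop=True)


def load_kinome(path, symbol_map: Mapping[str, str] | None = None) -> frozenset[str]:
    """Load the established protein-kinase catalog (one symbol per line)."""
    with open(path, encoding="utf-8") as handle:
        symbols = [line.strip().upper() for line in handle if line.strip() and not line.startswith("#")]
    if not symbols:
        raise InkaError("kinase catalog is empty")
    if symbol_map:
        symbols = list(map_symbols(symbols, symbol_map))
    return frozenset(symbols)


def load_knowledgebase(
    psp_path,
    networkin_path,
    activation_loop_path,
    kinome_path,
    symbol_map_path=None,
    networkin_min_score: float = NETWORKIN_MIN_SCORE,
    networkin_relative_fraction: float = NETWORKIN_RELATIVE_FRACTION,
) -> KnowledgeBase:
    """Load every annotation resource into a single :class:`KnowledgeBase`."""
    symbol_map = load_symbol_map(symbol_map_path) if symbol_map_path else {}
    psp = load_psp_relations(psp_path, symbol_map=symbol_map)
    nwk = load_networkin_relations(
        networkin_path,
        symbol_map=symbol_map,
        min_score=networkin_min_score,
        relative_fraction=networkin_relative_fraction,
    )
    return KnowledgeBase(
        relations=combine_relations(psp, nwk),
        activation_loops=load_activation_loops(activation_loop_path, symbol_map=symbol_map),
        kinome=load_kinome(kinome_path, symbol_map=symbol_map),
        symbol_map=dict(symbol_map),
    )
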