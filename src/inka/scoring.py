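"""Per-sample kinase-activity scoring.

Four evidence components are computed per kinase and sample:

* ``kinome`` — phosphosignal of every observed phosphopeptide derived from an
  established protein kinase (kinase-centric),
* ``activation_loop`` — the subset of kinome peptides annotated as lying in
  the kinase activation segment (kinase-centric; effectively a double weight
  on activation-loop phosphorylation),
* ``psp`` — phosphosignal of observed class-I substrate phosphosites linked
  to the kinase by curated relations (substrate-centric),
* ``nwk`` — same, for score-filtered predicted relations.

The phosphosignal of a peptide is its spectral count (or intensity)
multiplied by its number of phospho modifications; for substrate attribution
it is further divided by the number of class-I phosphosites inferred for the
peptide, so that a multiply-interpretable peptide is not over-credited.  The
integrated activity score is the geometric mean of the kinase-centric and
substrate-centric sums,

    C_kin  = C_kinome + C_activation_loop
    C_sub  = C_psp + C_nwk
    INKA   = sqrt(C_kin * C_sub)

so a non-zero score requires evidence on both sides.  A skew parameter in
[0, 1] locates each kinase between purely kinase-centric (0) and purely
substrate-centric (1) evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .knowledgebases import KnowledgeBase

logger = logging.getLogger(__name__)

COMPONENTS = ("kinome", "activation_loop", "psp", "nwk")

#: Default fraction of the top score a kinase needs to enter the scatter plot.
PLOT_FRACTION = 0.1
#: Default size of the ranked bar graph.
TOP_N = 20
#: Minimum raw spectral-count total for the out-of-scope bar graph.
MIN_OUT_OF_SCOPE_COUNTS = 2

SCORE_COLUMNS = [
    "c_kinome",
    "c_activation_loop",
    "c_psp",
    "c_nwk",
    "c_kin",
    "c_sub",
    "inka",
    "skew",
    "out_of_scope",
    "raw_total",
    "n_nonzero_evidence",
]


def phosphosignal_kinase_centric(quant, n_phospho):
    """Peptide phosphosignal: quantification times phospho-modification count."""
    return np.asarray(quant, dtype=float) * np.asarray(n_phospho, dtype=float)


def phosphosignal_substrate_centric(quant, n_phospho, n_inferred_sites):
    """Site-attribution phosphosignal: peptide phosphosignal split over the
    number of class-I phosphosites inferred for the peptide."""
    return phosphosignal_kinase_centric(quant, n_phospho) / np.asarray(
        n_inferred_sites, dtype=float
    )


def inka_score(c_kin, c_sub):
    """Geometric mean of kinase-centric and substrate-centric evidence sums."""
    c_kin = np.asarray(c_kin, dtype=float)
    c_sub = np.asarray(c_sub, dtype=float)
    if (c_kin < 0).any() or (c_sub < 0).any():
        raise ValueError("evidence sums must be non-negative")
    return np.sqrt(c_kin * c_sub)


def skew(c_kin, c_sub, formula: str = "sqrt"):
    """Normalized angular balance of substrate- vs kinase-centric evidence.

    0 when all evidence is kinase-centric, 1 when all is substrate-centric,
    0.5 for equal contributions; NaN when both sums are zero.  The default
    takes the angle of the point (sqrt(C_kin), sqrt(C_sub)); ``formula=
    "ratio"`` uses the angle of (C_kin, C_sub) instead — both hit the same
    anchor values.
    """
    c_kin = np.asarray(c_kin, dtype=float)
    c_sub = np.asarray(c_sub, dtype=float)
    if (c_kin < 0).any() or (c_sub < 0).any():
        raise ValueError("evidence sums must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.divide(c_sub, c_kin)
        if formula == "sqrt":
            angle = np.arctan(np.sqrt(ratio))
        elif formula == "ratio":
            angle = np.arctan(ratio)
        else:
            raise ValueError(f"unknown skew formula {formula!r}")
        out = (2.0 / np.pi) * angle
    out = np.where((c_kin == 0) & (c_sub > 0), 1.0, out)
    out = np.where((c_kin == 0) & (c_sub == 0), np.nan, out)
    if np.ndim(c_kin) == 0 and np.ndim(c_sub) == 0:
        return float(out)
    return out


def kinase_peptide_evidence(
    merged: pd.DataFrame, kb: KnowledgeBase, sample_id: str
) -> pd.DataFrame:
    """Kinase-centric evidence rows: one per observed kinase phosphopeptide.

    Distinct (gene, peptide, n_phospho) rows of the merged table whose gene is
    an established kinase; redundant site-level duplication is removed first.
    """
    cols = ["gene_symbol", "peptide_sequence", "n_phospho", sample_id]
    pep = merged[cols].drop_duplicates(["gene_symbol", "peptide_sequence", "n_phospho"])
    pep = pep[pep["gene_symbol"].isin(kb.kinome)].copy()
    pep = pep.rename(columns={sample_id: "quant"})
    pep["phosphosignal"] = phosphosignal_kinase_centric(pep["quant"], pep["n_phospho"])
    loops = set(map(tuple, kb.activation_loops[["gene_symbol", "peptide_sequence"]].to_numpy()))
    pep["is_activation_loop"] = pd.Series(
        [(g, p) in loops for g, p in zip(pep["gene_symbol"], pep["peptide_sequence"])],
        index=pep.index,
        dtype=bool,
    )
    return pep.reset_index(drop=True)


def substrate_site_evidence(
    merged: pd.DataFrame, kb: KnowledgeBase, sample_id: str
) -> pd.DataFrame:
    """Substrate-centric evidence rows: one per (kinase, matched site, source).

    The phosphosignals of all peptides harboring a class-I site are aggregated
    into a site phosphosignal, which is credited in full to every kinase
    linked to the site (no fractional splitting between kinases).
    """
    key = ["gene_symbol", "position", "residue"]
    contrib = merged[key + ["peptide_sequence", "n_phospho", "n_inferred_sites", sample_id]].copy()
    contrib["signal"] = phosphosignal_substrate_centric(
        contrib[sample_id], contrib["n_phospho"], contrib["n_inferred_sites"]
    )
    site_signal = contrib.groupby(key, as_index=False)["signal"].sum()

    rel = kb.relations.rename(columns={"substrate_symbol": "gene_symbol"})
    out = rel.merge(site_signal, on=key, how="inner")
    out = out.rename(
        columns={"gene_symbol": "substrate_symbol", "signal": "phosphosignal"}
    )
    out["site_key"] = (
        out["substrate_symbol"] + ":" + out["residue"] + out["position"].astype(str)
    )
    cols = [
        "kinase_symbol",
        "substrate_symbol",
        "position",
        "residue",
        "site_key",
        "source",
        "prediction_score",
        "phosphosignal",
    ]
    return out.sort_values(
        ["kinase_symbol", "substrate_symbol", "position", "source"], kind="mergesort"
    ).reset_index(drop=True)[cols]


@dataclass
class ComponentTable:
    """Per-kinase contributions and aggregate for one evidence component."""

    component: str
    sample_id: str
    contributions: pd.DataFrame  # kinase_symbol, evidence_key, phosphosignal
    aggregated: pd.Series  # kinase_symbol -> summed phosphosignal


def build_component(
    component: str, merged: pd.DataFrame, kb: KnowledgeBase, sample_id: str
) -> ComponentTable:
    """Assemble one of the four evidence components for a sample."""
    if component in ("kinome", "activation_loop"):
        pep = kinase_peptide_evidence(merged, kb, sample_id)
        if component == "activation_loop":
            pep = pep[pep["is_activation_loop"]]
        contrib = pd.DataFrame(
            {
                "kinase_symbol": pep["gene_symbol"],
                "evidence_key": pep["peptide_sequence"],
                "phosphosignal": pep["phosphosignal"],
            }
        )
    elif component in ("psp", "nwk"):
        sub = substrate_site_evidence(merged, kb, sample_id)
        sub = sub[sub["source"] == component.upper()]
        contrib = pd.DataFrame(
            {
                "kinase_symbol": sub["kinase_symbol"],
                "evidence_key": sub["site_key"],
                "phosphosignal": sub["phosphosignal"],
            }
        )
    else:
        raise ValueError(f"unknown component {component!r}")
    contrib = contrib.reset_index(drop=True)
    aggregated = contrib.groupby("kinase_symbol")["phosphosignal"].sum().sort_index()
    return ComponentTable(component, sample_id, contrib, aggregated)


def score_sample(
    merged: pd.DataFrame,
    kb: KnowledgeBase,
    sample_id: str,
    skew_formula: str = "sqrt",
) -> pd.DataFrame:
    """Compute the full per-kinase score table for one sample.

    Rows cover every kinase with any evidence: kinome-observed kinases (even
    with zero quantification in this sample) and kinases matched through
    relations.  Kinases with substrate evidence but no observed phosphopeptide
    get C_kin = 0 and hence a zero integrated score.
    """
    pep = kinase_peptide_evidence(merged, kb, sample_id)
    sub = substrate_site_evidence(merged, kb, sample_id)

    c_kinome = pep.groupby("gene_symbol")["phosphosignal"].sum()
    c_actloop = pep[pep["is_activation_loop"]].groupby("gene_symbol")["phosphosignal"].sum()
    c_psp = sub[sub["source"] == "PSP"].groupby("kinase_symbol")["phosphosignal"].sum()
    c_nwk = sub[sub["source"] == "NWK"].groupby("kinase_symbol")["phosphosignal"].sum()
    raw_total = pep.groupby("gene_symbol")["quant"].sum()
    n_nonzero = pep[pep["quant"] > 0].groupby("gene_symbol")["quant"].size()

    kinases = sorted(set(c_kinome.index) | set(c_psp.index) | set(c_nwk.index))
    if not kinases:
        logger.warning("no kinase evidence in sample %s", sample_id)
    table = pd.DataFrame(index=pd.Index(kinases, name="kinase_symbol"))
    table["c_kinome"] = c_kinome.reindex(kinases).fillna(0.0)
    table["c_activation_loop"] = c_actloop.reindex(kinases).fillna(0.0)
    table["c_psp"] = c_psp.reindex(kinases).fillna(0.0)
    table["c_nwk"] = c_nwk.reindex(kinases).fillna(0.0)
    table["c_kin"] = table["c_kinome"] + table["c_activation_loop"]
    table["c_sub"] = table["c_psp"] + table["c_nwk"]
    table["inka"] = inka_score(table["c_kin"], table["c_sub"])
    table["skew"] = skew(table["c_kin"], table["c_sub"], formula=skew_formula)
    oos = kb.out_of_scope()
    table["out_of_scope"] = [k in oos for k in kinases]
    table["raw_total"] = raw_total.reindex(kinases).fillna(0.0)
    table["n_nonzero_evidence"] = n_nonzero.reindex(kinases).fillna(0).astype(int)
    return table[SCORE_COLUMNS]


@dataclass
class InkaRanking:
    """Ranked outputs for one sample."""

    main: pd.DataFrame  # kinases with inka > 0, descending, "rank" column
    plot_set: pd.DataFrame  # >= plot_fraction of the top score
    bar_graph: pd.DataFrame  # top_n of the main ranking
    out_of_scope: pd.DataFrame  # catalog kinases absent from both resources


def _sorted_ranking(table: pd.DataFrame, by: str) -> pd.DataFrame:
    """Sort descending on ``by``, ties broken alphabetically, 1-based ranks."""
    out = table.copy()
    out["_sym"] = out.index
    out = out.sort_values([by, "_sym"], ascending=[False, True], kind="mergesort")
    out = out.drop(columns="_sym")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def rank_inka(
    scores: pd.DataFrame,
    plot_fraction: float = PLOT_FRACTION,
    top_n: int = TOP_N,
    min_out_of_scope_counts: float = MIN_OUT_OF_SCOPE_COUNTS,
    quant_mode: str = "counts",
) -> InkaRanking:
    """Derive the main ranking, plot set, bar-graph set, and out-of-scope bar.

    The out-of-scope bar ranks catalog kinases absent from both relation
    resources by kinase-centric evidence, keeping those with at least
    ``min_out_of_scope_counts`` raw spectral counts (in intensity mode: with
    at least two non-zero evidence rows), capped at ``top_n``.
    """
    if scores.empty:
        logger.warning("ranking requested on an empty score table")
        empty = scores.copy()
        empty["rank"] = pd.Series(dtype=int)
        return InkaRanking(empty, empty.copy(), empty.copy(), empty.copy())

    main = _sorted_ranking(scores[scores["inka"] > 0], "inka")
    if len(main):
        plot_set = main[main["inka"] >= plot_fraction * main["inka"].max()]
    else:
        plot_set = main.copy()
    bar = main.head(top_n)

    oos = scores[scores["out_of_scope"] & (scores["c_kin"] > 0)]
    if quant_mode == "intensity":
        oos = oos[oos["n_nonzero_evidence"] >= 2]
    else:
        oos = oos[oos["raw_total"] >= min_out_of_scope_counts]
    oos = _sorted_ranking(oos, "c_kin").head(top_n)
    return InkaRanking(main, plot_set, bar, oos)


def score_and_rank(
    merged: pd.DataFrame,
    kb: KnowledgeBase,
    sample_id: str,
    skew_formula: str = "sqrt",
    plot_fraction: float = PLOT_FRACTION,
    top_n: int = TOP_N,
    min_out_of_scope_counts: float = MIN_OUT_OF_SCOPE_COUNTS,
    quant_mode: str = "counts",
) -> tuple[pd.DataFrame, InkaRanking]:
    """Convenience wrapper: score a sample and rank it in one call."""
    scores = score_sample(merged, kb, sample_id, skew_formula=skew_formula)
    ranking = rank_inka(
        scores,
        plot_fraction=plot_fraction,
        top_n=top_n,
        min_out_of_scope_counts=min_out_of_scope_counts,
        quant_mode=quant_mode,
    )
    return scores, ranking
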