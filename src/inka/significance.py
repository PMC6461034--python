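"""Permutation null distributions and p-values for integrated activity scores.

Each iteration applies a double randomization jointly:

* experimental: all non-zero quantification values of the sample are permuted
  among the peptides that originally had non-zero values (zeros stay zero, the
  count multiset is conserved);
* annotation: every kinase-substrate relation keeps its substrate site but is
  re-attributed to a kinase drawn uniformly (with replacement) from the pool
  of distinct kinases present in the pooled relation tables.

Scores are recomputed on the randomized data, giving a sample- and
kinase-specific null distribution; the default is 100,000 iterations.  The
p-value is the one-sided upper tail with the plus-one correction,
p = (1 + #{null >= observed}) / (1 + n_iterations), which is never zero.
No multiple-testing correction is applied by default; Benjamini-Hochberg
adjusted values can be requested as a clearly labeled extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InkaError
from .knowledgebases import KnowledgeBase
from .scoring import score_sample

logger = logging.getLogger(__name__)

DEFAULT_ITERATIONS = 100_000


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the randomization procedure."""

    n_iterations: int = DEFAULT_ITERATIONS
    seed: int | None = None
    adjust: bool = False  # add Benjamini-Hochberg adjusted p-values

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def permute_experiment(
    merged: pd.DataFrame, sample_id: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute the sample's non-zero quantification values between peptides.

    Permutation acts at the level of distinct (peptide, n_phospho) entries so
    that site rows sharing a peptide stay consistent; rows that were zero
    remain zero.
    """
    out = merged.copy()
    key = ["peptide_sequence", "n_phospho"]
    uniq = out[key + [sample_id]].drop_duplicates(key).reset_index(drop=True)
    vals = uniq[sample_id].to_numpy(dtype=float, copy=True)
    nonzero = vals > 0
    vals[nonzero] = rng.permutation(vals[nonzero])
    uniq[sample_id] = vals
    out = out.drop(columns=sample_id).merge(uniq, on=key, how="left")
    return out


def randomize_relations(relations: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Re-attribute every relation to a random kinase from the pooled set."""
    if relations.empty:
        raise InkaError("cannot randomize an empty relation pool")
    pool = np.array(sorted(set(relations["kinase_symbol"])))
    out = relations.copy()
    out["kinase_symbol"] = pool[rng.integers(0, len(pool), len(out))]
    return out


class CompiledSample:
    """Index-array compilation of one sample for fast null-score iteration.

    Aggregates the merged table and knowledgebase into flat numpy arrays so
    that one null iteration costs a handful of bincounts.  The observed score
    vector computed here matches :func:`inka.scoring.score_sample` exactly
    (asserted in the test suite against the pandas path).
    """

    def __init__(self, merged: pd.DataFrame, kb: KnowledgeBase, sample_id: str):
        self.sample_id = sample_id

        pep_key = ["peptide_sequence", "n_phospho"]
        peptides = merged[pep_key + [sample_id]].drop_duplicates(pep_key).reset_index(drop=True)
        pep_index = {tuple(k): i for i, k in enumerate(peptides[pep_key].to_numpy())}
        self.counts = peptides[sample_id].to_numpy(dtype=float)
        self.n_phospho = peptides["n_phospho"].to_numpy(dtype=float)
        self.nonzero = self.counts > 0

        # kinase universe: observed kinome genes plus the relation kinase pool
        gp = merged[["gene_symbol", "peptide_sequence", "n_phospho"]].drop_duplicates()
        kin_gp = gp[gp["gene_symbol"].isin(kb.kinome)]
        pool = sorted(set(kb.relations["kinase_symbol"])) if len(kb.relations) else []
        self.kinases = sorted(set(kin_gp["gene_symbol"]) | set(pool))
        kin_index = {k: i for i, k in enumerate(self.kinases)}
        self.n_kinases = len(self.kinases)

        def _pep_rows(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
            kin = frame["gene_symbol"].map(kin_index).to_numpy(dtype=np.intp)
            pep = np.array(
                [pep_index[(s, n)] for s, n in zip(frame["peptide_sequence"], frame["n_phospho"])],
                dtype=np.intp,
            )
            return kin, pep

        self.kinome_kin, self.kinome_pep = _pep_rows(kin_gp)
        loops = set(map(tuple, kb.activation_loops[["gene_symbol", "peptide_sequence"]].to_numpy()))
        al = kin_gp[
            [
                (g, p) in loops
                for g, p in zip(kin_gp["gene_symbol"], kin_gp["peptide_sequence"])
            ]
        ]
        self.actloop_kin, self.actloop_pep = _pep_rows(al)

        # site contributions: unique (site, peptide) rows with divisors
        site_key = ["gene_symbol", "position", "residue"]
        contrib = merged[site_key + pep_key + ["n_inferred_sites"]].drop_duplicates(
            site_key + pep_key
        )
        sites = contrib[site_key].drop_duplicates().reset_index(drop=True)
        site_index = {tuple(k): i for i, k in enumerate(sites.to_numpy())}
        self.n_sites = len(sites)
        self.contrib_site = np.array(
            [site_index[tuple(r)] for r in contrib[site_key].to_numpy()], dtype=np.intp
        )
        self.contrib_pep = np.array(
            [pep_index[(s, n)] for s, n in zip(contrib["peptide_sequence"], contrib["n_phospho"])],
            dtype=np.intp,
        )
        self.contrib_div = contrib["n_inferred_sites"].to_numpy(dtype=float)

        # relations matched to observed sites (substrate symbol -> gene symbol)
        rel = kb.relations.rename(columns={"substrate_symbol": "gene_symbol"})
        rel = rel.merge(sites, on=site_key, how="inner")
        self.rel_site = np.array(
            [site_index[tuple(r)] for r in rel[site_key].to_numpy()], dtype=np.intp
        )
        self.rel_kin = rel["kinase_symbol"].map(kin_index).to_numpy(dtype=np.intp)
        self.pool_idx = np.array([kin_index[k] for k in pool], dtype=np.intp)

    def scores(self, counts: np.ndarray, rel_kin: np.ndarray) -> np.ndarray:
        """Integrated activity scores for a count vector and kinase assignment."""
        pep_sig = counts * self.n_phospho
        c_kin = np.bincount(
            self.kinome_kin, weights=pep_sig[self.kinome_pep], minlength=self.n_kinases
        )
        c_kin += np.bincount(
            self.actloop_kin, weights=pep_sig[self.actloop_pep], minlength=self.n_kinases
        )
        site_sig = np.bincount(
            self.contrib_site,
            weights=pep_sig[self.contrib_pep] / self.contrib_div,
            minlength=self.n_sites,
        )
        c_sub = np.bincount(rel_kin, weights=site_sig[self.rel_site], minlength=self.n_kinases)
        return np.sqrt(c_kin * c_sub)

    def observed(self) -> np.ndarray:
        return self.scores(self.counts, self.rel_kin)

    def null_scores(self, rng: np.random.Generator) -> np.ndarray:
        """One jointly randomized iteration of the null model."""
        counts = self.counts.copy()
        counts[self.nonzero] = rng.permutation(counts[self.nonzero])
        if len(self.pool_idx):
            rel_kin = self.pool_idx[rng.integers(0, len(self.pool_idx), len(self.rel_site))]
        else:
            rel_kin = self.rel_kin
        return self.scores(counts, rel_kin)


def inka_p_values(
    merged: pd.DataFrame,
    kb: KnowledgeBase,
    sample_id: str,
    config: PermutationConfig | None = None,
    rng: np.random.Generator | None = None,
    skew_formula: str = "sqrt",
) -> pd.DataFrame:
    """Score table for one sample with permutation p-values appended.

    Both randomizations are applied jointly in every iteration; the p-value
    per kinase is the plus-one upper-tail estimate against its own null.
    """
    config = config or PermutationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    table = score_sample(merged, kb, sample_id, skew_formula=skew_formula)
    compiled = CompiledSample(merged, kb, sample_id)
    observed = compiled.observed()

    obs_check = table["inka"].reindex(compiled.kinases).fillna(0.0).to_numpy()
    if not np.allclose(observed[np.isin(compiled.kinases, table.index)], obs_check[np.isin(compiled.kinases, table.index)]):
        raise InkaError("compiled observed scores disagree with the reference path")

    exceed = np.zeros(compiled.n_kinases, dtype=np.int64)
    for _ in range(config.n_iterations):
        exceed += compiled.null_scores(rng) >= observed
    p = (1.0 + exceed) / (1.0 + config.n_iterations)

    p_series = pd.Series(p, index=compiled.kinases)
    out = table.copy()
    out["p_value"] = p_series.reindex(out.index)
    if config.adjust:
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out
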