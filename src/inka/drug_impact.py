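"""Kinase impact scores: do top-ranked kinases attract potent drugs?

Given a kinase-activity ranking for a cell line, a table of per-cell-line
drug logIC50 values, and a binary drug-kinase target map g_ij, the *kinase
impact score* at list length N is

    sum over kinases i in the top-N and drugs j with g_ij = 1 of KAS_i * e_j

where KAS_i is the activity score normalized by the list maximum (so the top
kinase has KAS = 1) and e_j is the drug potency normalized per cell line:
logIC50 values are shifted by their median, negated, and divided by the
maximum absolute value, landing in [-1, 1] with high-affinity drugs positive.
High-ranking kinases targeted by potent drugs are rewarded; kinases targeted
by weak drugs are penalized.

Two ranking methods are compared by computing impact scores for every list
length from 2 to 40 and, per length, testing the per-sample paired
differences (Wilcoxon signed-rank by default; "paired Mann-Whitney" is a
contradiction, but an unpaired Mann-Whitney option is provided).  The
comparison is summarized by the median of the per-length p-values.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InkaError

logger = logging.getLogger(__name__)

DEFAULT_LENGTHS = range(2, 41)


def normalize_kas(scores: pd.Series) -> pd.Series:
    """Normalize an activity score list by its maximum, descending order.

    Ties keep alphabetical kinase order.  All-zero (or empty) lists are a
    fatal error: a ranking carries no information without a positive score.
    """
    s = pd.Series(scores, dtype=float)
    if s.empty or s.max() <= 0:
        raise InkaError("activity list needs at least one positive score")
    if (s < 0).any():
        raise InkaError("activity scores must be non-negative")
    out = s / s.max()
    frame = out.rename("kas").rename_axis("kinase").reset_index()
    frame = frame.sort_values(["kas", "kinase"], ascending=[False, True], kind="mergesort")
    return frame.set_index("kinase")["kas"]


def normalize_efficacy(log_ic50: pd.Series) -> pd.Series:
    """Normalize per-cell-line drug logIC50 values to potencies in [-1, 1].

    Median-center, negate, divide by the maximum absolute value; the median
    drug maps to 0 and the most potent drug to the positive extreme.  Zero
    spread yields all zeros with a warning.
    """
    s = pd.Series(log_ic50, dtype=float)
    if len(s) < 2:
        raise InkaError("need at least two drugs per cell line")
    shifted = -(s - s.median())
    denom = shifted.abs().max()
    if denom == 0:
        logger.warning("zero spread in logIC50 values: all potencies set to 0")
        return shifted
    return shifted / denom


def _target_pairs(targets) -> set[tuple[str, str]]:
    """Coerce a drug-kinase target map to a set of (drug, kinase) pairs."""
    if isinstance(targets, pd.DataFrame):
        return set(zip(targets["drug"].astype(str), targets["kinase"].astype(str)))
    if isinstance(targets, Mapping):
        return {(d, k) for (d, k), v in targets.items() if v}
    return set(targets)


def kinase_impact_score(
    kas: pd.Series,
    efficacy: pd.Series,
    targets,
    top_n: int,
) -> float:
    """Impact of the top-``top_n`` kinases of a normalized activity list.

    ``kas`` must be normalized and descending (see :func:`normalize_kas`);
    ``efficacy`` maps drug -> normalized potency; ``targets`` is a binary
    drug-kinase map (long DataFrame, mapping, or pair set).  Kinases absent
    from every drug's target set contribute nothing.
    """
    if top_n < 2:
        raise InkaError("list length must be at least 2")
    pairs = _target_pairs(targets)
    head = kas.iloc[:top_n]
    total = 0.0
    for kinase, activity in head.items():
        for drug, potency in efficacy.items():
            if (drug, kinase) in pairs:
                total += activity * potency
    return float(total)


def impact_profile(
    kas: pd.Series,
    efficacy: pd.Series,
    targets,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
) -> pd.Series:
    """Impact score at every requested list length (incremental computation)."""
    pairs = _target_pairs(targets)
    # per-kinase term: activity times the summed potency of its targeting drugs
    drug_sum = {
        kinase: sum(p for d, p in efficacy.items() if (d, kinase) in pairs)
        for kinase in kas.index
    }
    term = np.array([kas[k] * drug_sum[k] for k in kas.index])
    cumulative = np.concatenate([[0.0], np.cumsum(term)])
    lengths = list(lengths)
    values = [cumulative[min(n, len(kas))] for n in lengths]
    return pd.Series(values, index=pd.Index(lengths, name="n"), name="impact")


@dataclass
class MethodComparison:
    """Outcome of comparing two ranking methods over paired samples."""

    impacts: pd.DataFrame  # method, sample, n, impact
    per_length: pd.DataFrame  # n, p_value
    median_p: float


def _paired_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "wilcoxon":
        diff = a - b
        if np.allclose(diff, 0):
            return 1.0
        res = stats.wilcoxon(diff[diff != 0], alternative="two-sided", method="auto")
        return float(res.pvalue)
    if test == "mannwhitney":
        if np.allclose(a, b):
            return 1.0
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test {test!r}")


def compare_methods(
    method_a: Mapping[str, pd.Series],
    method_b: Mapping[str, pd.Series],
    efficacy: Mapping[str, pd.Series],
    targets,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    test: str = "wilcoxon",
    labels: tuple[str, str] = ("A", "B"),
) -> MethodComparison:
    """Compare two activity-ranking methods through impact scores.

    ``method_a`` / ``method_b`` map sample -> normalized activity list (both
    methods scored on the same samples), ``efficacy`` maps sample ->
    normalized drug potencies.  For every list length a paired nonparametric
    test on the per-sample impact scores is run; the comparison is summarized
    by the median of the per-length p-values.
    """
    samples = sorted(set(method_a) & set(method_b) & set(efficacy))
    if len(samples) < 2:
        raise InkaError("need at least two paired samples")
    lengths = list(lengths)

    rows = []
    for label, method in zip(labels, (method_a, method_b)):
        for sample in samples:
            profile = impact_profile(method[sample], efficacy[sample], targets, lengths)
            for n, value in profile.items():
                rows.append({"method": label, "sample": sample, "n": n, "impact": value})
    impacts = pd.DataFrame(rows)

    wide = impacts.pivot_table(index=["n", "sample"], columns="method", values="impact")
    p_rows = []
    for n in lengths:
        block = wide.loc[n]
        p = _paired_p(block[labels[0]].to_numpy(), block[labels[1]].to_numpy(), test)
        p_rows.append({"n": n, "p_value": p})
    per_length = pd.DataFrame(p_rows)
    return MethodComparison(impacts, per_length, float(per_length["p_value"].median()))


def read_efficacy_table(path) -> pd.DataFrame:
    """Read a (cell_line, drug, log_ic50) TSV; duplicate pairs are fatal."""
    frame = pd.read_csv(path, sep="\t")
    required = {"cell_line", "drug", "log_ic50"}
    if not required.issubset(frame.columns):
        raise InkaError(f"efficacy table needs columns {sorted(required)}")
    if frame.duplicated(["cell_line", "drug"]).any():
        raise InkaError("duplicate (cell_line, drug) rows in efficacy table")
    return frame


def read_target_table(path) -> pd.DataFrame:
    """Read a long-format (drug, kinase) target TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug", "kinase"}.issubset(frame.columns):
        raise InkaError("target table needs columns ['drug', 'kinase']")
    return frame.drop_duplicates().reset_index(drop=True)
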