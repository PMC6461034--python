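"""Synthetic phosphoproteomics experiments with known ground truth.

The generator emulates a phosphotyrosine-IP style experiment at toy scale:
a kinome of a few dozen kinases with 1-5 tryptic phosphopeptides each (the
first being the activation-loop peptide), a pool of substrate proteins with
class-I-mostly phosphosites, curated and predicted kinase-substrate relation
tables covering a configurable fraction of the kinome, and per-sample
spectral counts drawn from a Poisson background (or log-normal intensities).
One or more *driver* kinases are planted hyperactive: their own peptides and
the peptides carrying their substrate sites receive a fold-boosted mean.

Everything is written in the exact tab-separated dialects the readers
consume, so generated experiments exercise the full pipeline, including the
class-I filter (localization probabilities deliberately straddle 0.75), the
prediction-score filter (sub-threshold rows are planted), decoy/contaminant
dropping, and the out-of-scope path (uncovered kinases).  Regeneration with
the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_tables, knowledgebases
from .errors import InkaError
from .knowledgebases import KnowledgeBase

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQVW"))  # no K/R/S/T/Y inside peptides


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated experiment.

    Defaults describe the reference simulation: 50 kinases, Poisson(2)
    spectral-count background, one planted driver with a tenfold boost, and
    70% knowledgebase coverage (the rest of the kinome exercises the
    out-of-scope path).
    """

    n_kinases: int = 50
    n_substrates: int = 60
    n_samples: int = 1
    background_mean: float = 2.0
    driver_boost: float = 10.0
    n_drivers: int = 1
    kb_coverage: float = 0.7
    peptides_per_protein: tuple[int, int] = (1, 5)
    sites_per_peptide: tuple[int, int] = (1, 2)
    relations_per_kinase: tuple[int, int] = (1, 6)
    frac_low_localization: float = 0.15
    quant_mode: str = "counts"
    intensity_sigma: float = 1.0
    n_decoy_rows: int = 1
    n_contaminant_rows: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.driver_boost < 1:
            raise InkaError("driver fold-boost must be >= 1")
        if not 0 <= self.kb_coverage <= 1:
            raise InkaError("knowledgebase coverage must be in [0, 1]")
        if self.n_drivers > self.n_kinases:
            raise InkaError("more drivers than kinases")
        if min(self.n_kinases, self.n_substrates, self.n_samples) < 1:
            raise InkaError("sizes must be positive")
        if self.quant_mode not in ("counts", "intensity"):
            raise InkaError(f"unknown quant mode {self.quant_mode!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"sample{i + 1}" for i in range(self.n_samples)]


@dataclass
class SyntheticExperiment:
    """A generated bundle of pipeline inputs plus ground truth."""

    config: SyntheticConfig
    peptide_table: pd.DataFrame  # raw dialect, incl. decoy/contaminant rows
    site_table: pd.DataFrame  # raw dialect, probabilities straddle 0.75
    psp_table: pd.DataFrame  # PhosphoSitePlus dialect
    networkin_table: pd.DataFrame  # NetworKIN dialect, incl. sub-threshold rows
    activation_loops: pd.DataFrame
    kinome: list[str]
    symbol_map: pd.DataFrame
    drivers: list[str] = field(default_factory=list)
    covered: list[str] = field(default_factory=list)
    boosted_peptides: list[str] = field(default_factory=list)

    def knowledgebase(self) -> KnowledgeBase:
        """Parse the generated annotation tables into a knowledgebase."""
        psp = knowledgebases.parse_psp_frame(self.psp_table)
        nwk = knowledgebases.filter_networkin(
            knowledgebases.parse_networkin_frame(self.networkin_table)
        )
        return KnowledgeBase(
            relations=knowledgebases.combine_relations(psp, nwk),
            activation_loops=self.activation_loops.copy(),
            kinome=frozenset(self.kinome),
        )

    def merged_table(self) -> pd.DataFrame:
        """Run the generated tables through the reader/merge pipeline."""
        peptides = io_tables.process_peptide_frame(
            self.peptide_table, self.config.sample_ids, quant_mode=self.config.quant_mode
        )
        sites = io_tables.process_site_frame(self.site_table)
        return io_tables.merge_site_peptide(peptides, sites)

    def write(self, directory) -> dict[str, Path]:
        """Write every input file; byte-identical for a fixed seed."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "peptides": directory / "phosphopeptides.tsv",
            "sites": directory / "phosphosites.tsv",
            "psp": directory / "psp_kinase_substrate.tsv",
            "networkin": directory / "networkin_predictions.tsv",
            "activation_loops": directory / "activation_loops.tsv",
            "kinome": directory / "kinome.txt",
            "symbol_map": directory / "symbol_map.tsv",
        }
        kwargs = dict(sep="\t", index=False, lineterminator="\n", float_format="%.6g")
        self.peptide_table.to_csv(paths["peptides"], **kwargs)
        self.site_table.to_csv(paths["sites"], **kwargs)
        self.psp_table.to_csv(paths["psp"], **kwargs)
        self.networkin_table.to_csv(paths["networkin"], **kwargs)
        self.activation_loops.to_csv(paths["activation_loops"], **kwargs)
        paths["kinome"].write_text("\n".join(self.kinome) + "\n", encoding="utf-8")
        self.symbol_map.to_csv(paths["symbol_map"], **kwargs)
        return paths


def _random_peptide(rng: np.random.Generator, used: set[str]) -> str:
    """A unique tryptic-looking peptide (C-terminal K/R, no internal STY)."""
    while True:
        length = int(rng.integers(8, 16))
        body = "".join(rng.choice(_AMINO_ACIDS, size=length))
        seq = body + ("K" if rng.integers(2) else "R")
        if seq not in used:
            used.add(seq)
            return seq


def generate(config: SyntheticConfig | None = None, **overrides) -> SyntheticExperiment:
    """Generate a full synthetic experiment under the given study conditions."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    kinases = [f"KIN{i:03d}" for i in range(config.n_kinases)]
    substrates = [f"SUB{i:03d}" for i in range(config.n_substrates)]
    drivers = kinases[: config.n_drivers]

    # coverage: drivers are always scoreable; the remainder is drawn at random
    n_covered = max(int(round(config.kb_coverage * config.n_kinases)), 0)
    others = [k for k in kinases if k not in drivers]
    n_extra = max(n_covered - len(drivers), 0)
    covered = sorted(
        set(drivers) | set(rng.choice(others, size=min(n_extra, len(others)), replace=False))
    ) if config.kb_coverage > 0 else []

    # proteins -> peptides -> sites
    used: set[str] = set()
    pep_rows = []  # gene, sequence, n_phospho, is_activation_loop
    site_rows = []  # accession, gene, position, residue, prob, sequence
    gene_sites: dict[str, list[tuple[str, int, str, float]]] = {}
    lo_p, hi_p = config.peptides_per_protein
    lo_s, hi_s = config.sites_per_peptide
    for gene in kinases + substrates:
        n_pep = int(rng.integers(lo_p, hi_p + 1))
        position = int(rng.integers(50, 150))
        gene_sites[gene] = []
        for j in range(n_pep):
            seq = _random_peptide(rng, used)
            is_loop = gene in kinases and j == 0
            n_sites = int(rng.integers(lo_s, hi_s + 1))
            n_phospho = int(rng.integers(1, n_sites + 1))
            pep_rows.append((gene, seq, n_phospho, is_loop))
            for _ in range(n_sites):
                position += int(rng.integers(5, 40))
                if rng.random() >= config.frac_low_localization:
                    prob = float(rng.uniform(0.80, 1.0))
                else:
                    prob = float(rng.uniform(0.30, 0.75))
                site_rows.append((f"ACC_{gene}", gene, position, "Y", prob, seq))
                gene_sites[gene].append((seq, position, "Y", prob))

    # relations: covered kinases target random substrate sites
    all_sub_sites = [
        (gene, pos, res, prob, seq)
        for gene in substrates
        for seq, pos, res, prob in gene_sites[gene]
    ]
    classI_sub_sites = [s for s in all_sub_sites if s[3] > io_tables.CLASS_I_THRESHOLD]
    lo_r, hi_r = config.relations_per_kinase
    psp_rows, nwk_rows = [], []
    driver_sites: list[tuple[str, int]] = []
    for kin in covered:
        pool = classI_sub_sites if kin in drivers else all_sub_sites
        if not pool:
            continue
        for source_rows, is_nwk in ((psp_rows, False), (nwk_rows, True)):
            n_rel = int(rng.integers(lo_r, hi_r + 1))
            idx = rng.integers(0, len(pool), size=n_rel)
            for i in idx:
                gene, pos, res, _prob, _seq = pool[i]
                if kin in drivers:
                    driver_sites.append((gene, pos))
                if is_nwk:
                    nwk_rows.append(
                        (gene, pos, res, kin, "KIN", float(rng.uniform(2.0, 8.0)),
                         f"ENSP{int(rng.integers(1, 10**9)):011d}")
                    )
                else:
                    source_rows.append((kin, kin, gene, f"{res}{pos}", "human", "human"))
    # planted noise: sub-threshold predictions and non-human curated rows
    for _ in range(max(3, config.n_kinases // 10)):
        gene, pos, res, _prob, _seq = all_sub_sites[int(rng.integers(0, len(all_sub_sites)))]
        kin = kinases[int(rng.integers(0, len(kinases)))]
        nwk_rows.append(
            (gene, pos, res, kin, "KIN", float(rng.uniform(0.3, 1.9)),
             f"ENSP{int(rng.integers(1, 10**9)):011d}")
        )
        psp_rows.append((kin, kin, gene, f"{res}{pos}", "mouse", "mouse"))

    # driver-linked peptides get the boosted count mean
    driver_site_set = set(driver_sites)
    boosted = {seq for kin in drivers for seq, *_ in gene_sites[kin]}
    for gene in substrates:
        for seq, pos, _res, _prob in gene_sites[gene]:
            if (gene, pos) in driver_site_set:
                boosted.add(seq)

    # per-sample quantification
    quant_cols: dict[str, list[float]] = {sid: [] for sid in config.sample_ids}
    for gene, seq, _nph, _loop in pep_rows:
        mean = config.background_mean * (config.driver_boost if seq in boosted else 1.0)
        for sid in config.sample_ids:
            if config.quant_mode == "counts":
                quant_cols[sid].append(int(rng.poisson(mean)))
            else:
                quant_cols[sid].append(
                    float(rng.lognormal(np.log(1e6 * mean), config.intensity_sigma))
                )

    peptide_table = pd.DataFrame(
        {
            "Sequence": [r[1] for r in pep_rows],
            "Gene Names": [r[0] for r in pep_rows],
            "Phospho (STY)": [r[2] for r in pep_rows],
            **{sid: quant_cols[sid] for sid in config.sample_ids},
            "Reverse": "",
            "Potential contaminant": "",
        }
    )
    # planted decoy / contaminant rows (must be dropped by the reader)
    junk = []
    for flag, n_rows in (("Reverse", config.n_decoy_rows), ("Potential contaminant", config.n_contaminant_rows)):
        for _ in range(n_rows):
            junk.append(
                {
                    "Sequence": _random_peptide(rng, used),
                    "Gene Names": "DECOY" if flag == "Reverse" else "CONTAM",
                    "Phospho (STY)": 1,
                    **{sid: 1 for sid in config.sample_ids},
                    "Reverse": "+" if flag == "Reverse" else "",
                    "Potential contaminant": "+" if flag == "Potential contaminant" else "",
                }
            )
    if junk:
        peptide_table = pd.concat([peptide_table, pd.DataFrame(junk)], ignore_index=True)

    site_table = pd.DataFrame(
        site_rows,
        columns=["Protein", "Gene names", "Position", "Amino acid", "Localization prob", "Peptide sequence"],
    )
    psp_table = pd.DataFrame(
        psp_rows, columns=["KINASE", "GENE", "SUB_GENE", "SUB_MOD_RSD", "KIN_ORGANISM", "SUB_ORGANISM"]
    )
    networkin_table = pd.DataFrame(
        nwk_rows,
        columns=["substrate_name", "position", "residue", "id", "tree", "networkin_score", "string_identifier"],
    )
    activation_loops = pd.DataFrame(
        [(g, s) for g, s, _n, loop in pep_rows if loop],
        columns=["gene_symbol", "peptide_sequence"],
    )
    all_genes = kinases + substrates
    symbol_map = pd.DataFrame({"old_symbol": all_genes, "official_symbol": all_genes})

    return SyntheticExperiment(
        config=config,
        peptide_table=peptide_table,
        site_table=site_table,
        psp_table=psp_table,
        networkin_table=networkin_table,
        activation_loops=activation_loops,
        kinome=kinases,
        symbol_map=symbol_map,
        drivers=drivers,
        covered=list(covered),
        boosted_peptides=sorted(boosted),
    )


def generate_drug_tables(
    n_cell_lines: int = 4,
    n_drugs: int = 12,
    kinases: list[str] | None = None,
    targets_per_drug: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a drug-efficacy table and a binary drug-kinase target map.

    Returns ``(efficacy, targets)``: efficacy has one (cell_line, drug,
    log_ic50) row per pair with logIC50 ~ Normal(1, 1.5); targets is a long
    (drug, kinase) table.
    """
    rng = np.random.default_rng(seed)
    kinases = kinases or [f"KIN{i:03d}" for i in range(10)]
    cell_lines = [f"CL{i + 1}" for i in range(n_cell_lines)]
    drugs = [f"DRUG{i + 1:02d}" for i in range(n_drugs)]
    eff_rows = [
        {"cell_line": cl, "drug": d, "log_ic50": float(rng.normal(1.0, 1.5))}
        for cl in cell_lines
        for d in drugs
    ]
    lo, hi = targets_per_drug
    target_rows = []
    for d in drugs:
        n_targets = int(rng.integers(lo, hi + 1))
        for k in rng.choice(kinases, size=min(n_targets, len(kinases)), replace=False):
            target_rows.append({"drug": d, "kinase": str(k)})
    return pd.DataFrame(eff_rows), pd.DataFrame(target_rows)
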