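"""Synthetic single-cell splicing datasets with known ground truth.

The generator emulates the statistical structure of a full-length scRNA-seq
splicing study of pancreatic islets: K endocrine-like cell types under two
conditions (ND/T2D), cassette-exon inclusion levels with cell-type- and
condition-specific shifts, zero-inflated junction coverage, marker- and
maturity-gene expression, and flanking intron sequences with planted RBP
motifs.  Every quantity the downstream analysis estimates is emitted as a
truth table, so recovery can be tested end to end without any download.

Generative model
----------------
For each event a baseline inclusion level ``psi0 ~ Beta(a0, b0)``; non-null
events get a shifted level ``psi1 = psi0 +/- delta_psi`` in their target cell
type (``type_specific``) or in T2D cells (``condition_specific``).  Each
cell's inclusion level is drawn ``psi ~ Beta(c*psibar, c*(1-psibar))`` around
its class mean, with concentration ``c`` controlling cell-level
overdispersion.  Total junction reads ``T`` follow a zero-inflated negative
binomial; inclusion reads ``I ~ Binomial(T, 2*psi/(1+psi))`` and ``S = T - I``.
The inclusion-read probability is ``2*psi/(1+psi)`` rather than ``psi``
because inclusion is supported by two junctions, which makes the simulator
consistent with the estimator ``psi = (I/2)/(I/2+S)``.

Expression counts are negative binomial with per-type marker fold-changes, a
continuous per-cell maturity scalar in [0, 1] scaling a maturity gene set, and
a T2D fold-change on a dedicated differential-expression gene set kept
disjoint from the genes carrying condition-specific splicing (so splicing and
expression signals are statistically independent by construction).

Flanking sequences are i.i.d. uniform nucleotides; the focal motif is planted
in the exon-proximal upstream intron of regulated (non-null) events at rate
``p_plant`` and elsewhere at the background rate ``p_bg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (CassetteExonEvent, JunctionCounts, IUPAC_CODES,
                 reverse_complement, write_events, write_fasta,
                 write_junction_counts, write_run_config)

__all__ = ["SimConfig", "SimulatedDataset", "simulate_dataset",
           "truth_report", "write_dataset"]

EVENT_CLASSES = ("null", "type_specific", "condition_specific")
CONDITIONS = ("ND", "T2D")

_PSI_LO, _PSI_HI = 0.02, 0.98  # feasible band for planted class means


class SimConfigError(ValueError):
    """Raised for an infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset generator.

    Defaults describe a desk-scale islet-like experiment: 300 cells of three
    endocrine-like types under ND/T2D, 200 cassette exons with moderate
    junction coverage and dropout.
    """

    n_cells: int = 300
    n_events: int = 200
    cell_types: tuple = ("beta", "alpha", "dual")
    cell_type_proportions: tuple = (0.45, 0.40, 0.15)
    condition_proportions: tuple = (0.6, 0.4)  # ND, T2D
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"null": 0.8, "type_specific": 0.1,
                                 "condition_specific": 0.1})
    # inclusion-level model
    baseline_alpha: float = 2.0
    baseline_beta: float = 2.0
    delta_psi: float = 0.3
    concentration: float = 200.0
    # junction-coverage model (zero-inflated negative binomial)
    mean_reads: float = 30.0
    nb_dispersion: float = 5.0     # NB size; Var = mu + mu^2/size
    dropout: float = 0.3
    # expression model
    n_genes: int = 500
    n_marker_genes: int = 20       # per cell type
    marker_fold: float = 8.0
    n_maturity_genes: int = 20
    maturity_fold_range: float = 4.0   # expression ratio of m=1 vs m=0 cells
    n_condition_de_genes: int = 20
    condition_fold: float = 2.0
    expression_mean: float = 5.0
    expression_sigma: float = 1.0
    expression_nb_dispersion: float = 2.0
    # sequence / motif model
    motif: str = "GGGAGGG"
    p_plant: float = 0.8
    p_bg: float = 0.05
    up_len: int = 250
    down_len: int = 250
    cassette_len: int = 80
    flank_exon_len: int = 100
    intron_len: int = 300
    seed: int = 0

    def validate(self) -> None:
        for name, props in (("cell_type_proportions", self.cell_type_proportions),
                            ("condition_proportions", self.condition_proportions),
                            ("class_proportions",
                             tuple(self.class_proportions.values()))):
            if abs(sum(props) - 1.0) > 1e-9 or any(p < 0 for p in props):
                raise SimConfigError(f"{name} must be non-negative and sum to 1")
        if len(self.cell_type_proportions) != len(self.cell_types):
            raise SimConfigError("one proportion per cell type required")
        if set(self.class_proportions) - set(EVENT_CLASSES):
            raise SimConfigError(f"event classes must be among {EVENT_CLASSES}")
        if not 0 <= self.delta_psi <= 1:
            raise SimConfigError("delta_psi must be in [0, 1]")
        if _PSI_LO + self.delta_psi > _PSI_HI:
            raise SimConfigError(
                f"delta_psi={self.delta_psi} pushes planted class means outside "
                f"the feasible band [{_PSI_LO}, {_PSI_HI}]")
        if not 0 <= self.dropout <= 1:
            raise SimConfigError("dropout must be in [0, 1]")
        if not (0 <= self.p_plant <= 1 and 0 <= self.p_bg <= 1):
            raise SimConfigError("motif plant rates must be in [0, 1]")
        if self.intron_len < max(self.up_len, self.down_len):
            raise SimConfigError("intron_len must cover the requested flank length")
        needed = (self.n_events + len(self.cell_types) * self.n_marker_genes
                  + self.n_maturity_genes + self.n_condition_de_genes)
        if self.n_genes < needed:
            raise SimConfigError(
                f"n_genes={self.n_genes} too small for the structured gene sets "
                f"({needed} needed)")


@dataclass
class SimulatedDataset:
    """A complete synthetic dataset plus the truth tables behind it."""

    config: SimConfig
    events: list
    genome: dict
    junctions: JunctionCounts
    expression: pd.DataFrame          # cells x genes integer counts
    cells: pd.DataFrame               # cell_id, donor, condition, cell_type, maturity
    truth: pd.DataFrame               # per-event class, levels, planted-motif flag
    gene_sets: dict                   # name -> list of gene symbols

    def flanking_regions(self) -> pd.DataFrame:
        from .io import extract_flanking_regions
        return extract_flanking_regions(self.events, self.genome,
                                        up_len=self.config.up_len,
                                        down_len=self.config.down_len)


def _instantiate_motif(pattern: str, rng: np.random.Generator) -> str:
    """A concrete A/C/G/T realization of an IUPAC degenerate pattern."""
    out = []
    for letter in pattern:
        choices = sorted(IUPAC_CODES[letter] - {"N"}) or list("ACGT")
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _sample_baselines(rng, n, a0, b0, lo, hi):
    """Beta(a0,b0) draws rejected into [lo, hi]."""
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        if filled == n:
            break
        draw = rng.beta(a0, b0, size=n - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + ok.size] = ok
        filled += ok.size
    else:
        raise SimConfigError("could not sample baseline psi in the feasible band")
    return out


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset; byte-reproducible given ``config.seed``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # independent sub-streams so e.g. changing the expression model does not
    # perturb junction sampling
    (ss_events, ss_cells, ss_psi, ss_cov, ss_expr, ss_seq) = root.spawn(6)
    rng_ev = np.random.default_rng(ss_events)
    rng_cell = np.random.default_rng(ss_cells)
    rng_psi = np.random.default_rng(ss_psi)
    rng_cov = np.random.default_rng(ss_cov)
    rng_expr = np.random.default_rng(ss_expr)
    rng_seq = np.random.default_rng(ss_seq)

    K = len(config.cell_types)
    n_cells, n_events = config.n_cells, config.n_events
    gene_names = [f"G{i:04d}" for i in range(config.n_genes)]

    # --- cells -----------------------------------------------------------
    type_idx = rng_cell.choice(K, size=n_cells, p=config.cell_type_proportions)
    cond_idx = rng_cell.choice(2, size=n_cells, p=config.condition_proportions)
    maturity = rng_cell.uniform(0.0, 1.0, size=n_cells)
    donors = {"ND": [f"ND{i+1}" for i in range(5)],
              "T2D": [f"T2D{i+1}" for i in range(3)]}
    cell_rows = []
    for i in range(n_cells):
        cond = CONDITIONS[cond_idx[i]]
        cell_rows.append({
            "cell_id": f"C{i:04d}",
            "donor": donors[cond][rng_cell.integers(len(donors[cond]))],
            "condition": cond,
            "cell_type": config.cell_types[type_idx[i]],
            "maturity": maturity[i],
        })
    cells = pd.DataFrame(cell_rows).set_index("cell_id", drop=False)

    # --- events and true inclusion levels --------------------------------
    classes = rng_ev.choice(len(EVENT_CLASSES), size=n_events,
                            p=[config.class_proportions.get(c, 0.0)
                               for c in EVENT_CLASSES])
    target_type = rng_ev.integers(K, size=n_events)
    sign = rng_ev.choice([-1.0, 1.0], size=n_events)
    psi0 = np.empty(n_events)
    psi1 = np.empty(n_events)
    for j in range(n_events):
        if classes[j] == 0:
            psi0[j] = _sample_baselines(rng_ev, 1, config.baseline_alpha,
                                        config.baseline_beta, _PSI_LO, _PSI_HI)[0]
            psi1[j] = psi0[j]
        else:
            if sign[j] > 0:
                lo, hi = _PSI_LO, _PSI_HI - config.delta_psi
            else:
                lo, hi = _PSI_LO + config.delta_psi, _PSI_HI
            psi0[j] = _sample_baselines(rng_ev, 1, config.baseline_alpha,
                                        config.baseline_beta, lo, hi)[0]
            psi1[j] = psi0[j] + sign[j] * config.delta_psi

    # class-mean matrix psibar[cell, event]
    psibar = np.broadcast_to(psi0, (n_cells, n_events)).copy()
    is_type = classes == 1
    is_cond = classes == 2
    for j in np.flatnonzero(is_type):
        psibar[type_idx == target_type[j], j] = psi1[j]
    for j in np.flatnonzero(is_cond):
        psibar[cond_idx == 1, j] = psi1[j]

    c = config.concentration
    psi_cell = rng_psi.beta(c * psibar, c * (1.0 - psibar))
    psi_cell = np.clip(psi_cell, 1e-9, 1 - 1e-9)

    # --- junction counts -------------------------------------------------
    size = config.nb_dispersion
    p_nb = size / (size + config.mean_reads)
    T = rng_cov.negative_binomial(size, p_nb, size=(n_cells, n_events))
    T[rng_cov.random((n_cells, n_events)) < config.dropout] = 0
    p_incl = 2.0 * psi_cell / (1.0 + psi_cell)
    I = rng_cov.binomial(T, p_incl)
    S = T - I
    cell_ids = list(cells["cell_id"])
    event_ids = [f"E{j:04d}" for j in range(n_events)]
    junctions = JunctionCounts(cell_ids, event_ids, I.astype(np.int64),
                               S.astype(np.int64))

    # --- genome, event coordinates and motif planting --------------------
    flank, intr, cas = config.flank_exon_len, config.intron_len, config.cassette_len
    block = 2 * flank + 2 * intr + cas + 20
    genome_len = block * n_events
    seq = rng_seq.integers(4, size=genome_len)
    bases = np.array(list("ACGT"))
    strands = np.where(rng_seq.random(n_events) < 0.5, "+", "-")
    planted = np.zeros(n_events, dtype=bool)
    motif_real = _instantiate_motif(config.motif, rng_seq)
    mlen = len(motif_real)
    motif_codes = np.array(["ACGT".index(b) for b in motif_real])
    rc_codes = np.array(["ACGT".index(b)
                         for b in reverse_complement(motif_real)])

    def plant(window_start: int, window_len: int, strand: str) -> None:
        pos = int(rng_seq.integers(window_len - mlen + 1))
        codes = motif_codes if strand == "+" else rc_codes
        seq[window_start + pos: window_start + pos + mlen] = codes

    events = []
    for j in range(n_events):
        o = j * block
        a = (o, o + flank)
        b = (o + flank + intr, o + flank + intr + cas)
        d = (o + flank + 2 * intr + cas, o + 2 * flank + 2 * intr + cas)
        strand = strands[j]
        if strand == "+":
            up_exon, down_exon = a, d
            up_window = (b[0] - config.up_len, config.up_len)   # 5' flank
            down_window = (b[1], config.down_len)
        else:
            up_exon, down_exon = d, a
            up_window = (b[1], config.up_len)
            down_window = (b[0] - config.down_len, config.down_len)
        rate = config.p_plant if classes[j] != 0 else config.p_bg
        if rng_seq.random() < rate:
            plant(*up_window, strand)
            planted[j] = True
        if rng_seq.random() < config.p_bg:
            plant(*down_window, strand)
        events.append(CassetteExonEvent(
            event_id=event_ids[j], gene=gene_names[j], chrom="chr1",
            strand=strand, up_exon=up_exon, cassette=b, down_exon=down_exon))
    genome = {"chr1": "".join(bases[seq])}

    # --- expression ------------------------------------------------------
    marker_start = n_events
    maturity_start = marker_start + K * config.n_marker_genes
    de_start = maturity_start + config.n_maturity_genes
    gene_sets = {"maturity": gene_names[maturity_start:de_start],
                 "condition_de": gene_names[de_start:
                                            de_start + config.n_condition_de_genes]}
    for k, t in enumerate(config.cell_types):
        lo = marker_start + k * config.n_marker_genes
        gene_sets[f"markers_{t}"] = gene_names[lo:lo + config.n_marker_genes]

    base_mu = rng_expr.lognormal(np.log(config.expression_mean),
                                 config.expression_sigma, size=config.n_genes)
    mu = np.broadcast_to(base_mu, (n_cells, config.n_genes)).copy()
    for k in range(K):
        lo = marker_start + k * config.n_marker_genes
        hi = lo + config.n_marker_genes
        mu[np.ix_(type_idx == k, np.arange(lo, hi))] *= config.marker_fold
    mat_factor = config.maturity_fold_range ** (maturity - 0.5)
    mu[:, maturity_start:de_start] *= mat_factor[:, None]
    mu[np.ix_(cond_idx == 1, np.arange(de_start,
                                       de_start + config.n_condition_de_genes))] \
        *= config.condition_fold
    depth = rng_expr.lognormal(0.0, 0.3, size=n_cells)
    mu *= depth[:, None]
    esize = config.expression_nb_dispersion
    counts = rng_expr.negative_binomial(esize, esize / (esize + mu))
    expression = pd.DataFrame(counts.astype(np.int64), index=cell_ids,
                              columns=gene_names)

    truth = pd.DataFrame({
        "event_id": event_ids,
        "gene": gene_names[:n_events],
        "event_class": [EVENT_CLASSES[k] for k in classes],
        "target_type": [config.cell_types[t] if k == 1 else ""
                        for k, t in zip(classes, target_type)],
        "psi_baseline": psi0,
        "psi_shifted": psi1,
        "strand": strands,
        "motif_planted": planted,
    }).set_index("event_id", drop=False)

    return SimulatedDataset(config=config, events=events, genome=genome,
                            junctions=junctions, expression=expression,
                            cells=cells, truth=truth, gene_sets=gene_sets)


def truth_report(dataset: SimulatedDataset) -> pd.DataFrame:
    """True delta-psi per event for every contrast the analysis runs.

    One-vs-rest contrasts report the planted shift of the target type against
    the unshifted baseline; the condition contrast reports T2D minus ND.
    """
    cfg = dataset.config
    rows = []
    for _, ev in dataset.truth.iterrows():
        shift = ev["psi_shifted"] - ev["psi_baseline"]
        rows.append({"event_id": ev["event_id"], "contrast": "T2D_vs_ND",
                     "event_class": ev["event_class"],
                     "true_delta_psi":
                         shift if ev["event_class"] == "condition_specific" else 0.0})
        for t in cfg.cell_types:
            rows.append({
                "event_id": ev["event_id"], "contrast": f"{t}_vs_rest",
                "event_class": ev["event_class"],
                "true_delta_psi":
                    shift if (ev["event_class"] == "type_specific"
                              and ev["target_type"] == t) else 0.0})
    return pd.DataFrame(rows)


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write every component in the package's standard text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_events(dataset.events, outdir / "events.tsv")
    write_fasta(dataset.genome, outdir / "genome.fa")
    write_junction_counts(dataset.junctions, outdir / "junctions_I.tsv",
                          outdir / "junctions_S.tsv")
    dataset.expression.to_csv(outdir / "expression.tsv", sep="\t")
    dataset.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    dataset.truth.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    truth_report(dataset).to_csv(outdir / "truth_contrasts.tsv", sep="\t",
                                 index=False)
    with open(outdir / "gene_sets.tsv", "w") as fh:
        fh.write("set\tgene\n")
        for name, genes in dataset.gene_sets.items():
            for g in genes:
                fh.write(f"{name}\t{g}\n")
    write_run_config(outdir, asdict(dataset.config))
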