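"""Synthetic genomes, counts, event tables and spectral counts with ground truth.

The generator emulates the statistical structure the analyses assume:

* per-gene intron windows with a planted number of ACTAA core motifs
  (0, 1, or >= 2 — the dual class drawn as either two independent cores or a
  tandem-embedded TACTAACTAAC), on rejection-sampled backgrounds so the
  scanner sees exactly the planted occurrences and nothing else;
* two-condition, replicated negative-binomial counts for unspliced and
  spliced transcript rows, with a splicing-repression effect (an increase in
  the unspliced fraction, in percentage points) planted in motif-bearing
  genes under induction;
* two-contrast dPSI tables with planted quadrant structure and confidence
  values;
* spectral-count tables with planted substrate-specific enrichment over an
  aptamer-only background.

A single integer seed drives everything through numpy SeedSequence spawning,
so every fixture is reproducible stream-by-stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ClassedCountMatrix,
    GenomeSequence,
    IntronAnnotation,
    SpectralCountTable,
    reverse_complement,
)
from .motif_scan import scan_motif

__all__ = [
    "SimulationConfig",
    "AnnotationTruth",
    "simulate_annotation",
    "simulate_counts",
    "simulate_dpsi_tables",
    "simulate_spectral_counts",
    "simulate_dia_quant",
]

CORE = "ACTAA"
TANDEM_EMBEDDED = "TACTAACTAAC"  # two overlapping ACTAA cores
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the splicing-repression simulation.

    Defaults model a compact yeast-like induction experiment: 300 genes at
    20% intronless, three replicates per condition, negative-binomial counts
    with dispersion 0.05 around log-normal expression (median ~660 counts,
    so nearly all genes clear the base-mean > 100 filter), baseline unspliced
    fractions from Beta(2, 18) (mean 10%), and a planted 30-point increase in
    percent unspliced for affected genes under induction.  Motif classes
    {0, 1, >= 2 cores} default to (0.55, 0.30, 0.15); the chance a gene is
    affected rises with its motif content (0 / 0.5 / 1.0 by class).
    """

    seed: int = 0
    n_genes: int = 300
    intronless_fraction: float = 0.2
    motif_class_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)
    affected_prob_by_class: tuple[float, float, float] = (0.0, 0.5, 1.0)
    n_reps: int = 3
    baseline_beta: tuple[float, float] = (2.0, 18.0)
    effect_delta: float = 30.0
    nb_dispersion: float = 0.05
    mean_expression: tuple[float, float] = (6.5, 0.8)  # log-normal mu, sigma
    window_len: int = 80
    intron_len_range: tuple[int, int] = (150, 400)
    exon_len: int = 100
    flank_len: int = 20
    tandem_fraction: float = 0.5  # of the dual class, planted tandem-embedded

    def __post_init__(self) -> None:
        if abs(sum(self.motif_class_probs) - 1.0) > 1e-9:
            raise ValueError("motif_class_probs must sum to 1")
        if not 0.0 <= self.intronless_fraction <= 1.0:
            raise ValueError("intronless_fraction outside [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.window_len < len(TANDEM_EMBEDDED) + 1:
            raise ValueError("window too short to plant a tandem-embedded site")
        if self.intron_len_range[0] < self.window_len:
            raise ValueError("introns must be at least one window long")


@dataclass
class AnnotationTruth:
    """Planted ground truth, one row per gene.

    Columns: gene_id, intronless, motif_class, n_cores, core_positions
    (window offsets, comma-joined), tandem_embedded, baseline_fraction,
    affected, induced_fraction.
    """

    genes: pd.DataFrame


def _rng_streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _core_free_seq(rng: np.random.Generator, length: int, max_tries: int = 200) -> str:
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if not scan_motif(seq, CORE):
            return seq
    raise RuntimeError("rejection sampling failed to produce a core-free sequence")


def _plant_window(
    rng: np.random.Generator, cfg: SimulationConfig, motif_class: int
) -> tuple[str, list[int], bool]:
    """Window with exactly ``motif_class`` core hits (2 for the dual class)."""
    L = cfg.window_len
    for _ in range(500):
        seq = _core_free_seq(rng, L)
        tandem = False
        if motif_class == 0:
            positions: list[int] = []
        elif motif_class == 1:
            p = int(rng.integers(0, L - len(CORE) + 1))
            seq = seq[:p] + CORE + seq[p + len(CORE):]
            positions = [p]
        else:
            tandem = bool(rng.random() < cfg.tandem_fraction)
            if tandem:
                p = int(rng.integers(0, L - len(TANDEM_EMBEDDED) + 1))
                seq = seq[:p] + TANDEM_EMBEDDED + seq[p + len(TANDEM_EMBEDDED):]
                positions = [p + 1, p + 5]  # the two overlapping cores
            else:
                # two independent, non-overlapping cores
                p1 = int(rng.integers(0, L - 2 * len(CORE)))
                p2 = int(rng.integers(p1 + len(CORE), L - len(CORE) + 1))
                seq = seq[:p1] + CORE + seq[p1 + len(CORE):]
                seq = seq[:p2] + CORE + seq[p2 + len(CORE):]
                positions = [p1, p2]
        hits = [h.offset for h in scan_motif(seq, CORE)]
        want = {0: 0, 1: 1, 2: 2}[motif_class]
        if len(hits) == want and hits == positions:
            return seq, positions, tandem
    raise RuntimeError("could not plant window with the requested core count")


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, GenomeSequence], list[IntronAnnotation], AnnotationTruth]:
    """Genome contigs, intron annotation and per-gene planted truth.

    Each gene sits on its own contig (flank-exon-intron-exon-flank in
    transcript orientation; minus-strand genes are stored reverse
    complemented).  The last ``window_len`` intron nucleotides carry exactly
    the planted core occurrences; everything else in the window is
    rejection-sampled core-free.
    """
    streams = _rng_streams(config.seed, ["layout", "seq", "truth"])
    layout, seq_rng, truth_rng = (
        streams["layout"], streams["seq"], streams["truth"]
    )
    genomes: dict[str, GenomeSequence] = {}
    introns: list[IntronAnnotation] = []
    rows = []
    a, b = config.baseline_beta
    for i in range(config.n_genes):
        gene = f"g{i:04d}"
        chrom = f"chr_{gene}"
        intronless = bool(layout.random() < config.intronless_fraction)
        strand = "+" if layout.random() < 0.5 else "-"
        if intronless:
            tx = _random_seq(seq_rng, config.flank_len * 2 + config.exon_len * 2)
            genomes[chrom] = GenomeSequence(
                chrom, tx if strand == "+" else reverse_complement(tx)
            )
            rows.append(
                {
                    "gene_id": gene,
                    "intronless": True,
                    "strand": strand,
                    "motif_class": -1,
                    "n_cores": 0,
                    "core_positions": "",
                    "tandem_embedded": False,
                    "baseline_fraction": np.nan,
                    "affected": False,
                    "induced_fraction": np.nan,
                }
            )
            continue
        motif_class = int(
            layout.choice(3, p=np.asarray(config.motif_class_probs))
        )
        window, positions, tandem = _plant_window(seq_rng, config, motif_class)
        ilen = int(layout.integers(*config.intron_len_range))
        intron_seq = _random_seq(seq_rng, ilen - config.window_len) + window
        tx = (
            _random_seq(seq_rng, config.flank_len)
            + _random_seq(seq_rng, config.exon_len)
            + intron_seq
            + _random_seq(seq_rng, config.exon_len)
            + _random_seq(seq_rng, config.flank_len)
        )
        L = len(tx)
        tx_start = config.flank_len + config.exon_len  # intron, transcript coords
        tx_end = tx_start + ilen
        if strand == "+":
            genome_seq, start, end = tx, tx_start, tx_end
        else:
            genome_seq, start, end = reverse_complement(tx), L - tx_end, L - tx_start
        genomes[chrom] = GenomeSequence(chrom, genome_seq)
        introns.append(
            IntronAnnotation(
                intron_id=f"{gene}.intron1",
                gene_id=gene,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
            )
        )
        baseline = float(truth_rng.beta(a, b))
        affected = bool(
            truth_rng.random() < config.affected_prob_by_class[motif_class]
        )
        induced = baseline + (config.effect_delta / 100.0 if affected else 0.0)
        induced = float(np.clip(induced, 0.0, 1.0))
        rows.append(
            {
                "gene_id": gene,
                "intronless": False,
                "strand": strand,
                "motif_class": motif_class,
                "n_cores": len(positions),
                "core_positions": ",".join(map(str, positions)),
                "tandem_embedded": tandem,
                "baseline_fraction": baseline,
                "affected": affected,
                "induced_fraction": induced,
            }
        )
    genes_df = pd.DataFrame(rows).set_index("gene_id", drop=False)
    genes_df.index.name = None
    truth = AnnotationTruth(genes_df)
    return genomes, introns, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson as disp->0)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    annotation: Sequence[IntronAnnotation],
    truth: AnnotationTruth,
    config: SimulationConfig,
) -> ClassedCountMatrix:
    """Replicated two-condition counts for every gene in the truth table.

    Per gene g and sample s: total expression lambda_gs ~ log-normal;
    unspliced ~ NB(lambda * f), spliced ~ NB(lambda * (1 - f)) with the
    gene-shared dispersion, where f is the baseline unspliced fraction, or
    the induced fraction in induced samples of affected genes.  Intronless
    genes emit a single NB(lambda) row.  Same config (and seed) gives
    byte-identical output.
    """
    rng = _rng_streams(config.seed, ["counts"])["counts"]
    mu, sigma = config.mean_expression
    control = [f"ctrl_{r + 1}" for r in range(config.n_reps)]
    induced = [f"qki5_{r + 1}" for r in range(config.n_reps)]
    samples = control + induced
    conditions = pd.Series(
        {**{s: "control" for s in control}, **{s: "induced" for s in induced}}
    )
    index, data, classes, genes = [], [], {}, {}
    for row in truth.genes.itertuples(index=False):
        lam = rng.lognormal(mu, sigma, size=len(samples))
        if row.intronless:
            tid = f"{row.gene_id}_m"
            index.append(tid)
            data.append(_nb_draw(rng, lam, config.nb_dispersion))
            classes[tid], genes[tid] = "intronless", row.gene_id
            continue
        frac = np.array(
            [
                row.baseline_fraction if conditions[s] == "control"
                else row.induced_fraction
                for s in samples
            ]
        )
        tid_u, tid_s = f"{row.gene_id}_pre", f"{row.gene_id}_m"
        index.extend([tid_u, tid_s])
        data.append(_nb_draw(rng, lam * frac, config.nb_dispersion))
        data.append(_nb_draw(rng, lam * (1.0 - frac), config.nb_dispersion))
        classes[tid_u], genes[tid_u] = "unspliced", row.gene_id
        classes[tid_s], genes[tid_s] = "spliced", row.gene_id
    df = pd.DataFrame(np.vstack(data), index=index, columns=samples)
    return ClassedCountMatrix(
        df, pd.Series(classes), pd.Series(genes), conditions
    )


DEFAULT_QUADRANT_PROBS: dict[str, float] = {
    "upA_downB": 0.215,
    "upA_upB": 0.10,
    "downA_downB": 0.10,
    "downA_upB": 0.085,
    "null": 0.5,
}


def simulate_dpsi_tables(
    n_events: int = 500,
    quadrant_probs: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    mv_margin: float = 10.0,
    seed: int = 0,
    min_magnitude: float = 12.0,
    max_magnitude: float = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-contrast dPSI tables with planted quadrant structure.

    Quadrant events get |dPSI| in [min_magnitude, max_magnitude] (plus
    optional Gaussian noise, re-clamped so they stay confidently above the
    |dPSI| > 10 cutoff) with signs per quadrant and MVdPSI95 =
    max(|dPSI| - mv_margin, 0.5) > 0.  Null events have |dPSI| < 1 and
    MVdPSI95 = 0.  Returns (table_a, table_b, truth); tables have columns
    event_id, event_type, gene_id, dpsi, mv, truth adds true_quadrant and a
    base_mean expression column for control selection.
    """
    probs = dict(quadrant_probs or DEFAULT_QUADRANT_PROBS)
    labels = list(probs)
    p = np.asarray([probs[l] for l in labels], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("quadrant_probs must sum to 1")
    rng = np.random.default_rng(seed)
    sign = {
        "upA_downB": (1, -1),
        "upA_upB": (1, 1),
        "downA_downB": (-1, -1),
        "downA_upB": (-1, 1),
    }
    rows_a, rows_b, truth_rows = [], [], []
    for i in range(n_events):
        label = labels[int(rng.choice(len(labels), p=p))]
        event = f"ev{i:05d}"
        gene = f"evg{i:05d}"
        etype = "AltEx" if rng.random() < 0.8 else "RI"
        base_mean_val = float(rng.lognormal(6.0, 1.0))
        if label == "null":
            da = float(rng.uniform(-0.9, 0.9))
            db = float(rng.uniform(-0.9, 0.9))
            mva = mvb = 0.0
        else:
            sa, sb = sign[label]
            mag_a = float(rng.uniform(min_magnitude, max_magnitude))
            mag_b = float(rng.uniform(min_magnitude, max_magnitude))
            if noise_sd > 0:
                mag_a += float(rng.normal(0, noise_sd))
                mag_b += float(rng.normal(0, noise_sd))
            mag_a = float(np.clip(mag_a, 11.0, 100.0))
            mag_b = float(np.clip(mag_b, 11.0, 100.0))
            da, db = sa * mag_a, sb * mag_b
            mva = max(mag_a - mv_margin, 0.5)
            mvb = max(mag_b - mv_margin, 0.5)
        rows_a.append(
            {"event_id": event, "event_type": etype, "gene_id": gene,
             "dpsi": da, "mv": mva}
        )
        rows_b.append(
            {"event_id": event, "event_type": etype, "gene_id": gene,
             "dpsi": db, "mv": mvb}
        )
        truth_rows.append(
            {"event_id": event, "gene_id": gene, "true_quadrant": label,
             "base_mean": base_mean_val}
        )
    return (
        pd.DataFrame(rows_a),
        pd.DataFrame(rows_b),
        pd.DataFrame(truth_rows),
    )


def simulate_spectral_counts(
    n_proteins: int = 100,
    enrichment_map: Mapping[str, tuple[str, float]] | None = None,
    seed: int = 0,
    substrates: Sequence[str] = ("WT", "upDEL", "dnDEL", "2xDEL"),
    background_level: float = 0.05,
    noise_sd: float = 0.1,
) -> tuple[SpectralCountTable, pd.DataFrame]:
    """NE/APT/substrate spectral counts with planted enrichment.

    ``enrichment_map`` assigns protein id -> (substrate, fold): the protein's
    background-corrected enrichment in that substrate is planted at about
    ``fold``.  Unlisted proteins sit at aptamer-background level in every
    substrate, so their corrected enrichment averages ~0.  The NE column is
    strictly positive.  Returns the table plus a truth frame with columns
    protein_id, enriched_substrate, fold.
    """
    enrichment_map = dict(enrichment_map or {})
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    unknown = set(enrichment_map) - set(proteins)
    if unknown:
        raise ValueError(f"enrichment_map names unknown proteins: {sorted(unknown)}")
    ne = rng.lognormal(np.log(20.0), 0.5, size=n_proteins)
    apt = ne * background_level * rng.lognormal(0.0, noise_sd, size=n_proteins)
    data = {"NE": ne, "APT": apt}
    for s in substrates:
        col = apt * rng.lognormal(0.0, noise_sd, size=n_proteins)
        data[s] = col
    df = pd.DataFrame(data, index=proteins)
    truth_rows = []
    for i, protein in enumerate(proteins):
        sub, fold = enrichment_map.get(protein, (None, 0.0))
        if sub is not None:
            if sub not in substrates:
                raise ValueError(f"unknown substrate {sub!r} for {protein}")
            df.loc[protein, sub] = apt[i] + fold * ne[i] * float(
                rng.lognormal(0.0, noise_sd)
            )
        truth_rows.append(
            {"protein_id": protein, "enriched_substrate": sub, "fold": fold}
        )
    roles = {"NE": "NE", "APT": "APT", **{s: "substrate" for s in substrates}}
    return SpectralCountTable(df, roles), pd.DataFrame(truth_rows)


def simulate_dia_quant(
    n_proteins: int = 60,
    enriched: Mapping[str, float] | None = None,
    n_reps: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    group_num: str = "dnDEL",
    group_den: str = "WT",
    missing_fraction: float = 0.0,
) -> tuple[SpectralCountTable, pd.DataFrame]:
    """Replicate-column DIA-style quant table with planted log2 fold changes.

    ``enriched`` maps protein id -> true log2FC (numerator over denominator);
    other proteins have true log2FC 0.  Gaussian noise of ``noise_sd`` is
    added on the log2 scale.  ``missing_fraction`` of cells are blanked to
    NaN to exercise the missing-value exclusion rule.
    """
    enriched = dict(enriched or {})
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    unknown = set(enriched) - set(proteins)
    if unknown:
        raise ValueError(f"enriched names unknown proteins: {sorted(unknown)}")
    base = rng.lognormal(np.log(1000.0), 0.6, size=n_proteins)
    cols = {}
    for r in range(n_reps):
        cols[f"{group_den}_{r + 1}"] = base * 2.0 ** rng.normal(
            0.0, noise_sd, size=n_proteins
        )
    lfc = np.array([enriched.get(p, 0.0) for p in proteins])
    for r in range(n_reps):
        cols[f"{group_num}_{r + 1}"] = base * 2.0 ** (
            lfc + rng.normal(0.0, noise_sd, size=n_proteins)
        )
    df = pd.DataFrame(cols, index=proteins)
    if missing_fraction > 0:
        mask = rng.random(df.shape) < missing_fraction
        df = df.mask(mask)
    roles = {
        c: f"replicate:{group_den}" for c in df.columns if c.startswith(group_den)
    }
    roles.update(
        {c: f"replicate:{group_num}" for c in df.columns if c.startswith(group_num)}
    )
    truth = pd.DataFrame({"protein_id": proteins, "true_log2fc": lfc})
    return SpectralCountTable(df, roles), truth
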