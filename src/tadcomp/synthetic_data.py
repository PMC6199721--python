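"""Seed-deterministic synthetic datasets with planted domain structure.

The generator emulates the statistical structure the analysis assumes so
every pipeline stage is testable without downloads:

* one latent repressive state per chromosome segment, realized into three
  correlated domain flavors (LAD / Null / Black) via per-flavor
  concordance probabilities — so nested Venn-style overlaps arise from a
  single ground truth;
* two gene dosage classes (X male = 1 dose; X female and autosomes = 2),
  with expression lower but non-zero inside repressive segments and a
  silent fraction below the detection cutoffs;
* a multiplicative compensation model on male X expression — MSL boost on
  occupied non-repressive genes, gene-network feedback everywhere, and
  regional derepression inside repressive domains (layers compose
  additively in log2);
* sex-specific ChIP enrichment (MOF / H4K16Ac / MSL-1) concentrated on
  occupied non-repressive X genes, delivered as tiled 25-bp windows;
* entry sites depleted from repressive segments by a configurable odds
  ratio while raw motif copies are planted uniformly;
* knockdown conditions that remove the MSL factor from occupied genes
  only.

All outputs are deterministic functions of (config, seed); the fixture
bundle round-trips through plain-text files byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chip_signal import SignalTrack, read_signal_track
from .expression_metrics import ExpressionTable
from .genome_domains import (
    DomainSet,
    GeneModel,
    GenomicInterval,
    classify_chrom,
    read_domain_bed,
    read_gene_models,
    write_domain_bed,
    write_gene_tsv,
)
from .motif_mre import read_sites

__all__ = [
    "CompensationModel",
    "ExpressionModel",
    "ChipModel",
    "EntrySiteModel",
    "MotifModel",
    "SimConfig",
    "SampleSpec",
    "Genome",
    "FixtureBundle",
    "KD_CONDITIONS",
    "generate_genome",
    "generate_expression",
    "generate_chip_tracks",
    "default_samples",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

#: Conditions that disable the MSL layer on occupied genes.
KD_CONDITIONS = frozenset({"kd_mof", "kd_msl1", "kd_msl2", "kd_msl3", "rox_null"})
VALID_CONDITIONS = KD_CONDITIONS | {"control"}


@dataclass
class CompensationModel:
    """Multiplicative layers of male X dosage compensation.

    ``msl_factor`` applies to non-repressive X genes with planted MSL
    occupancy; ``derepression_factor`` to repressive-domain X genes in
    males; ``network_factor`` to every one-dose gene. Unset factors
    default so that the product of applicable layers is exactly 2.0 (full
    compensation) on both routes: ``derepression = 2 / network`` and a
    ``residual_factor = 2 / (msl * network)`` tops up occupied genes.
    """

    msl_factor: float = 1.4
    network_factor: float = 1.1
    derepression_factor: float | None = None
    residual_factor: float | None = None
    enabled: bool = True

    def resolved_derepression(self) -> float:
        if self.derepression_factor is not None:
            return self.derepression_factor
        return 2.0 / self.network_factor

    def resolved_residual(self) -> float:
        if self.residual_factor is not None:
            return self.residual_factor
        return 2.0 / (self.msl_factor * self.network_factor)

    def male_x_factor(
        self, occupied: bool, repressive: bool, condition: str = "control"
    ) -> float:
        """Compensation multiplier for a one-dose male X gene."""
        if not self.enabled:
            return 1.0
        f = self.network_factor
        if repressive:
            f *= self.resolved_derepression()
        elif occupied:
            msl = 1.0 if condition in KD_CONDITIONS else self.msl_factor
            f *= msl * self.resolved_residual()
        return f


@dataclass
class ExpressionModel:
    """Log2-scale expression baselines and noise."""

    baseline_mean_non_repressive: float = 5.0
    baseline_mean_repressive: float = 3.0
    baseline_sd: float = 1.5
    silent_fraction_repressive: float = 0.4
    silent_fraction_non_repressive: float = 0.1
    silent_mean: float = -4.0
    silent_sd: float = 1.0
    noise_sd: float = 0.2
    n_replicates: int = 3
    array_offset: float = 0.5
    intergenic_mean: float = -4.0
    intergenic_sd: float = 1.6
    n_intergenic: int = 5000
    control_probe_mean: float = 2.0
    control_probe_sd: float = 0.3
    n_control_probes: int = 2000


@dataclass
class ChipModel:
    """Gene-body ChIP means (M-value scale) by class, per 25-bp window."""

    occupied_x_male: float = 1.5
    occupied_x_female: float = 0.3
    repressive_x_male: float = 0.2
    repressive_x_female: float = 0.1
    background: float = 0.0
    window_sd: float = 0.3
    window_size: int = 25
    knockdown_attenuation: float = 0.35
    target_scales: dict = field(
        default_factory=lambda: {
            "MOF": 1.0,
            "H4K16ac": 1.0,
            "MSL1": 0.8,
            "H3K36me3": 0.6,
        }
    )


@dataclass
class EntrySiteModel:
    """Chromosome entry sites on the X, depleted from repressive segments."""

    n_sites: int = 150
    width: int = 100
    depletion_odds: float = 0.25


@dataclass
class MotifModel:
    """A 21-bp GA-rich recognition-element motif planted uniformly."""

    consensus: str = "GAGAGCGAGAGGAAAGAGAGA"
    spacing: int = 10_000
    site_mutation_rate: float = 0.02
    n_training_sites: int = 150


@dataclass
class SimConfig:
    """Full description of a simulated study."""

    chrom_lengths: dict = field(
        default_factory=lambda: {"X": 1_500_000, "2L": 2_250_000, "2R": 2_250_000}
    )
    x_chroms: tuple = ("X",)
    n_genes: dict = field(default_factory=lambda: {"X": 500, "2L": 750, "2R": 750})
    gene_length_range: tuple = (500, 2000)
    non_coding_fraction: float = 0.05
    repressive_fraction: float = 0.2
    segment_length_range: tuple = (40_000, 120_000)
    concordance: dict = field(
        default_factory=lambda: {"LAD": 0.9, "Null": 0.95, "Black": 0.9}
    )
    occupancy_prob_non_repressive: float = 1.0
    occupancy_prob_repressive: float = 0.0
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    compensation: CompensationModel = field(default_factory=CompensationModel)
    chip: ChipModel = field(default_factory=ChipModel)
    entry_sites: EntrySiteModel = field(default_factory=EntrySiteModel)
    motif: MotifModel = field(default_factory=MotifModel)

    @classmethod
    def default_study(cls) -> "SimConfig":
        """The default study conditions (~2,000 genes, full compensation)."""
        return cls()

    @classmethod
    def uncompensated(cls) -> "SimConfig":
        """Same genome, but no male X compensation (expect log2 M/F = -1)."""
        cfg = cls()
        cfg.compensation = CompensationModel(enabled=False)
        return cfg

    @classmethod
    def small(cls) -> "SimConfig":
        """A reduced genome for fast smoke/determinism tests."""
        cfg = cls()
        cfg.chrom_lengths = {"X": 300_000, "2L": 400_000}
        cfg.n_genes = {"X": 100, "2L": 140}
        cfg.entry_sites = EntrySiteModel(n_sites=40)
        cfg.expression = ExpressionModel(n_intergenic=2000, n_control_probes=500)
        # with so few latent segments, fully concordant flavors keep the
        # overlap classes populated
        cfg.concordance = {"LAD": 1.0, "Null": 1.0, "Black": 1.0}
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    sex: str  # F or M
    source: str  # e.g. kc, s2, sg
    condition: str  # control, kd_mof, ...
    platform: str  # rnaseq or array


@dataclass
class Genome:
    """In-memory synthetic genome with planted ground truth."""

    genes: list
    domain_sets: dict  # name -> DomainSet
    latent_segments: dict  # chrom -> list[GenomicInterval]
    sequences: dict  # chrom -> str
    entry_sites: list  # list[GenomicInterval] on the X
    training_sites: list  # aligned site sequences for PWM construction
    motif_truth: pd.DataFrame  # chrom, start, strand
    gene_truth: pd.DataFrame  # indexed by gene_id
    config: SimConfig
    seed: int


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_FROM_BASE = {b: i for i, b in enumerate("ACGT")}


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def _slot_placement(length: int, n: int, item_len_lo: int, item_len_hi: int, rng):
    """Place n non-overlapping items by jittering one item per equal slot."""
    slot = length // n
    if slot <= item_len_lo + 2:
        raise ValueError(
            f"infeasible packing: {n} items of >= {item_len_lo} bp on {length} bp"
        )
    out = []
    for i in range(n):
        hi = min(item_len_hi, slot - 2)
        item_len = int(rng.integers(item_len_lo, hi + 1))
        start = i * slot + int(rng.integers(0, slot - item_len + 1))
        out.append((start, start + item_len))
    return out


def _contained_in(segments: list, start: int, end: int) -> bool:
    return any(s.start <= start and end <= s.end for s in segments)


def _overlaps_any(segments: list, start: int, end: int) -> bool:
    return any(s.start < end and start < s.end for s in segments)


def generate_genome(config: SimConfig, seed: int) -> Genome:
    """Generate genes, domain calls, sequence, entry sites and motif truth."""
    rng = np.random.default_rng(seed)
    expr = config.expression
    latent_segments: dict[str, list[GenomicInterval]] = {}
    genes: list[GeneModel] = []
    truth_rows = []
    sequences: dict[str, str] = {}
    motif_rows = []
    consensus = config.motif.consensus.upper()
    width = len(consensus)
    cons_codes = np.array([_CODE_FROM_BASE[b] for b in consensus], dtype=np.uint8)
    rc_codes = (3 - cons_codes)[::-1]

    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        # latent repressive segments
        seg_lo, seg_hi = config.segment_length_range
        mean_seg = (seg_lo + seg_hi) / 2
        n_seg = max(1, round(length * config.repressive_fraction / mean_seg))
        segs = [
            GenomicInterval(chrom, s, e)
            for s, e in _slot_placement(length, n_seg, seg_lo, seg_hi, rng)
        ]
        latent_segments[chrom] = segs

        # genes
        n_genes = config.n_genes[chrom]
        g_lo, g_hi = config.gene_length_range
        chrom_class = classify_chrom(chrom, config.x_chroms)
        for i, (s, e) in enumerate(
            _slot_placement(length, n_genes, g_lo, g_hi, rng)
        ):
            gene_id = f"g{chrom}_{i:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = (
                "ncRNA"
                if rng.random() < config.non_coding_fraction
                else "protein_coding_polyA"
            )
            latent = _contained_in(segs, s, e)
            if chrom_class == "X":
                occ_p = (
                    config.occupancy_prob_repressive
                    if latent
                    else config.occupancy_prob_non_repressive
                )
                occupied = bool(rng.random() < occ_p)
            else:
                occupied = False
            silent_frac = (
                expr.silent_fraction_repressive
                if latent
                else expr.silent_fraction_non_repressive
            )
            silent = bool(rng.random() < silent_frac)
            if silent:
                baseline = rng.normal(expr.silent_mean, expr.silent_sd)
            else:
                mean = (
                    expr.baseline_mean_repressive
                    if latent
                    else expr.baseline_mean_non_repressive
                )
                baseline = rng.normal(mean, expr.baseline_sd)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    interval=GenomicInterval(chrom, s, e),
                    strand=strand,
                    biotype=biotype,
                    chrom_class=chrom_class,
                )
            )
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "chrom_class": chrom_class,
                    "latent_repressive": latent,
                    "occupied": occupied,
                    "silent": silent,
                    "baseline_log2": float(baseline),
                }
            )

        # sequence with planted motif copies, uniform along the chromosome
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        n_planted = max(1, length // config.motif.spacing)
        for s, _ in _slot_placement(length, n_planted, width, width, rng):
            plant_rc = rng.random() < 0.5
            codes[s : s + width] = rc_codes if plant_rc else cons_codes
            motif_rows.append(
                {"chrom": chrom, "start": s, "strand": "-" if plant_rc else "+"}
            )
        sequences[chrom] = _codes_to_str(codes)

    # domain flavors: each latent segment is called in a flavor with the
    # configured concordance probability, so flavors share one ground truth
    domain_sets = {}
    for flavor in sorted(config.concordance):
        conc = config.concordance[flavor]
        intervals = []
        for chrom in sorted(latent_segments):
            for seg in latent_segments[chrom]:
                if rng.random() < conc:
                    intervals.append(seg)
        domain_sets[flavor] = DomainSet(
            name=flavor, intervals=intervals, source="synthetic"
        )

    # entry sites on the X, depleted from repressive segments
    es = config.entry_sites
    x_chrom = sorted(set(config.x_chroms) & set(config.chrom_lengths))[0]
    x_len = config.chrom_lengths[x_chrom]
    x_segs = latent_segments[x_chrom]
    frac = sum(len(s) for s in x_segs) / x_len
    p_in = es.depletion_odds * frac / (es.depletion_odds * frac + (1 - frac))
    seg_lengths = np.array([len(s) for s in x_segs], dtype=float)
    entry_sites = []
    for _ in range(es.n_sites):
        if rng.random() < p_in:
            seg = x_segs[rng.choice(len(x_segs), p=seg_lengths / seg_lengths.sum())]
            start = int(rng.integers(seg.start, seg.end - es.width + 1))
        else:
            while True:
                start = int(rng.integers(0, x_len - es.width + 1))
                if not _overlaps_any(x_segs, start, start + es.width):
                    break
        entry_sites.append(GenomicInterval(x_chrom, start, start + es.width))

    # aligned training sites (low-diversity copies of the consensus)
    training_sites = []
    for _ in range(config.motif.n_training_sites):
        site = cons_codes.copy()
        mutate = rng.random(width) < config.motif.site_mutation_rate
        if mutate.any():
            site[mutate] = (site[mutate] + rng.integers(1, 4, mutate.sum())) % 4
        training_sites.append(_codes_to_str(site))

    gene_truth = pd.DataFrame(truth_rows).set_index("gene_id")
    motif_truth = pd.DataFrame(motif_rows, columns=["chrom", "start", "strand"])
    return Genome(
        genes=genes,
        domain_sets=domain_sets,
        latent_segments=latent_segments,
        sequences=sequences,
        entry_sites=entry_sites,
        training_sites=training_sites,
        motif_truth=motif_truth,
        gene_truth=gene_truth,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def default_samples(config: SimConfig) -> list[SampleSpec]:
    """The standard sample sheet: sexed cell-line RNA-seq, sexed salivary
    gland arrays, and a male knockdown array experiment with its control."""
    n = config.expression.n_replicates
    specs = []
    for sex, source, condition, platform in (
        ("F", "kc", "control", "rnaseq"),
        ("M", "s2", "control", "rnaseq"),
        ("F", "sg", "control", "array"),
        ("M", "sg", "control", "array"),
        ("M", "s2", "control", "array"),
        ("M", "s2", "kd_mof", "array"),
    ):
        for rep in range(1, n + 1):
            specs.append(
                SampleSpec(
                    sample_id=f"{source}_{sex}_{condition}_{platform}_r{rep}",
                    sex=sex,
                    source=source,
                    condition=condition,
                    platform=platform,
                )
            )
    return specs


def generate_expression(
    genome: Genome,
    samples: Sequence[SampleSpec] | None = None,
    seed: int = 0,
) -> tuple[ExpressionTable, dict]:
    """Expression values for each sample, plus background measurements.

    Linear-scale expression is ``2^baseline x dose x compensation x
    2^noise``; male X genes carry dose 0.5 and the configured
    compensation layers; knockdown conditions drop the MSL layer from
    occupied genes. Array samples report ``log2(value + offset)``.
    Returns ``(table, aux)`` with ``aux["intergenic"]`` FPKM background
    values and ``aux["control_probes"]`` array background intensities.
    """
    config = genome.config
    expr = config.expression
    comp = config.compensation
    if samples is None:
        samples = default_samples(config)
    for spec in samples:
        if spec.condition not in VALID_CONDITIONS:
            raise ValueError(f"unknown condition: {spec.condition!r}")
    rng = np.random.default_rng(seed)
    truth = genome.gene_truth
    base_lin = 2.0 ** truth["baseline_log2"].to_numpy()
    is_x = (truth["chrom_class"] == "X").to_numpy()
    occupied = truth["occupied"].to_numpy()
    latent = truth["latent_repressive"].to_numpy()
    n_genes = len(truth)
    factors_cache: dict[str, np.ndarray] = {}

    def male_factors(condition: str) -> np.ndarray:
        if condition not in factors_cache:
            f = np.ones(n_genes)
            for i in np.nonzero(is_x)[0]:
                f[i] = 0.5 * comp.male_x_factor(
                    bool(occupied[i]), bool(latent[i]), condition
                )
            factors_cache[condition] = f
        return factors_cache[condition]

    columns = {}
    meta_rows = []
    for spec in samples:
        scale = male_factors(spec.condition) if spec.sex == "M" else np.ones(n_genes)
        noise = rng.normal(0.0, expr.noise_sd, n_genes)
        value = base_lin * scale * 2.0**noise
        if spec.platform == "array":
            value = np.log2(value + expr.array_offset)
        columns[spec.sample_id] = value
        meta_rows.append(
            {
                "sample_id": spec.sample_id,
                "sex": spec.sex,
                "source": spec.source,
                "condition": spec.condition,
                "platform": spec.platform,
            }
        )
    values = pd.DataFrame(columns, index=truth.index.copy())
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    aux = {
        "intergenic": 2.0
        ** rng.normal(expr.intergenic_mean, expr.intergenic_sd, expr.n_intergenic),
        "control_probes": rng.normal(
            expr.control_probe_mean, expr.control_probe_sd, expr.n_control_probes
        ),
    }
    return ExpressionTable(values=values, samples=meta), aux


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------


def _gene_chip_mean(
    chip: ChipModel,
    target: str,
    sex: str,
    chrom_class: str,
    occupied: bool,
    repressive: bool,
    condition: str,
) -> float:
    scale = chip.target_scales.get(target, 1.0)
    male = sex == "M"
    if chrom_class != "X":
        level = chip.background
    elif repressive:
        level = chip.repressive_x_male if male else chip.repressive_x_female
    elif occupied:
        level = chip.occupied_x_male if male else chip.occupied_x_female
    else:
        level = chip.background
    if (
        condition in KD_CONDITIONS
        and male
        and occupied
        and not repressive
        and chrom_class == "X"
    ):
        level *= chip.knockdown_attenuation
    return level * scale


def generate_chip_tracks(
    genome: Genome,
    sex: str,
    target: str = "MOF",
    seed: int = 0,
    condition: str = "control",
) -> SignalTrack:
    """Tiled windowed ChIP scores whose per-window mean follows gene class.

    Windows tile every chromosome at the configured size (default 25 bp);
    windows overlapping a gene body take that gene's class mean, others
    the background mean; Gaussian window noise is added on top.
    """
    if condition not in VALID_CONDITIONS:
        raise ValueError(f"unknown condition: {condition!r}")
    config = genome.config
    chip = config.chip
    rng = np.random.default_rng(seed)
    w = chip.window_size
    frames = []
    truth = genome.gene_truth
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_win = length // w
        starts = np.arange(n_win, dtype=np.int64) * w
        means = np.full(n_win, chip.background * chip.target_scales.get(target, 1.0))
        chrom_genes = [g for g in genome.genes if g.chrom == chrom]
        for gene in chrom_genes:
            row = truth.loc[gene.gene_id]
            mean = _gene_chip_mean(
                chip,
                target,
                sex,
                gene.chrom_class,
                bool(row["occupied"]),
                bool(row["latent_repressive"]),
                condition,
            )
            lo = gene.start // w
            hi = (gene.end + w - 1) // w
            means[lo : min(hi, n_win)] = mean
        scores = means + rng.normal(0.0, chip.window_sd, n_win)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + w, "score": scores}
            )
        )
    return SignalTrack(windows=pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """Materialized view of a written fixture directory."""

    genes: list
    domain_sets: dict
    sequences: dict
    entry_sites: list
    training_sites: list
    gene_truth: pd.DataFrame
    motif_truth: pd.DataFrame
    expression: ExpressionTable | None
    aux: dict
    tracks: dict  # (target, sex, condition) -> SignalTrack
    manifest: dict


def _write_fasta(sequences: Mapping[str, str], path, line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fixture_bundle(
    genome: Genome,
    directory,
    expression: ExpressionTable | None = None,
    aux: dict | None = None,
    tracks: Mapping[tuple, SignalTrack] | None = None,
) -> dict:
    """Write the full fixture as plain-text files plus a manifest.

    Returns the manifest dict (also written as ``manifest.json``). A
    round-trip through :func:`read_fixture_bundle` reproduces the
    in-memory objects exactly, and two bundles generated from the same
    config and seed are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []

    def record(name: str):
        files.append(name)
        return directory / name

    _write_fasta(genome.sequences, record("genome.fa"))
    write_gene_tsv(genome.genes, record("genes.tsv"))
    for name, dset in sorted(genome.domain_sets.items()):
        write_domain_bed(dset, record(f"domains_{name}.bed"))
    with open(record("entry_sites.bed"), "w") as fh:
        for i, iv in enumerate(genome.entry_sites):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tces_{i}\n")
    with open(record("training_sites.fa"), "w") as fh:
        for i, site in enumerate(genome.training_sites):
            fh.write(f">site_{i}\n{site}\n")
    genome.motif_truth.to_csv(record("motif_truth.tsv"), sep="\t", index=False)
    genome.gene_truth.to_csv(record("gene_truth.tsv"), sep="\t", index_label="gene_id")
    if expression is not None:
        expression.to_tsv(record("expression.tsv"), record("samples.tsv"))
    if aux:
        for key in sorted(aux):
            pd.Series(aux[key], name="value").to_csv(
                record(f"{key}.tsv"), sep="\t", index=False
            )
    if tracks:
        (directory / "tracks").mkdir(exist_ok=True)
        for key in sorted(tracks):
            target, sex, condition = key
            name = f"tracks/{target}_{sex}_{condition}.tsv"
            tracks[key].windows.to_csv(
                record(name), sep="\t", index=False, header=False
            )
    manifest = {
        "seed": genome.seed,
        "config_hash": genome.config.config_hash(),
        "config": genome.config.to_dict(),
        "files": sorted(files),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return manifest


def read_fixture_bundle(directory) -> FixtureBundle:
    """Read back a fixture bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    x_chroms = tuple(manifest["config"]["x_chroms"])
    genes = read_gene_models(directory / "genes.tsv", format="tsv", x_names=x_chroms)
    domain_sets = {}
    for path in sorted(directory.glob("domains_*.bed")):
        name = path.stem.replace("domains_", "", 1)
        domain_sets[name] = read_domain_bed(path, name=name)
    entry_sites = []
    with open(directory / "entry_sites.bed") as fh:
        for line in fh:
            chrom, start, end = line.split("\t")[:3]
            entry_sites.append(GenomicInterval(chrom, int(start), int(end)))
    sequences = _read_fasta(directory / "genome.fa")
    training_sites = read_sites(directory / "training_sites.fa")
    gene_truth = pd.read_csv(
        directory / "gene_truth.tsv",
        sep="\t",
        index_col="gene_id",
        float_precision="round_trip",
    )
    motif_truth = pd.read_csv(directory / "motif_truth.tsv", sep="\t")
    expression = None
    if (directory / "expression.tsv").exists():
        expression = ExpressionTable.from_tsv(
            directory / "expression.tsv", directory / "samples.tsv"
        )
    aux = {}
    for key in ("intergenic", "control_probes"):
        path = directory / f"{key}.tsv"
        if path.exists():
            aux[key] = pd.read_csv(
                path, sep="\t", float_precision="round_trip"
            )["value"].to_numpy()
    tracks = {}
    track_dir = directory / "tracks"
    if track_dir.exists():
        for path in sorted(track_dir.glob("*.tsv")):
            target, sex, condition = path.stem.split("_", 2)
            tracks[(target, sex, condition)] = read_signal_track(path)
    return FixtureBundle(
        genes=genes,
        domain_sets=domain_sets,
        sequences=sequences,
        entry_sites=entry_sites,
        training_sites=training_sites,
        gene_truth=gene_truth,
        motif_truth=motif_truth,
        expression=expression,
        aux=aux,
        tracks=tracks,
        manifest=manifest,
    )
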