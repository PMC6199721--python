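"""Gene models, domain calls, and gene-to-domain assignment.

Coordinates are 0-based half-open everywhere inside the package. GFF3
input (1-based closed) is converted on read; BED passes through.

A gene belongs to a domain only when *both* of its boundaries lie inside a
single (merged) domain interval — genes straddling a domain edge are not
members. Domain intervals within one set are merged (overlapping and
book-ended fragments coalesce) before assignment so the containment rule is
well defined across adjacent fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import resampling

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "DomainSet",
    "GeneDomainAssignment",
    "ContingencyTable2x2",
    "DomainPartition",
    "DEFAULT_X_NAMES",
    "DEFAULT_BIOTYPE",
    "classify_chrom",
    "merge_intervals",
    "read_gene_models",
    "read_domain_bed",
    "write_domain_bed",
    "write_gene_tsv",
    "assign_genes_to_domains",
    "domain_overlap_partition",
    "chromosome_enrichment",
]

DEFAULT_X_NAMES: tuple[str, ...] = ("X", "chrX")
DEFAULT_BIOTYPE = "protein_coding_polyA"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located feature on a named chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """Non-strict containment: boundary equality counts as inside."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def classify_chrom(chrom: str, x_names: Sequence[str] = DEFAULT_X_NAMES) -> str:
    """Map a chromosome name to ``"X"`` or ``"autosome"``."""
    return "X" if chrom in x_names else "autosome"


@dataclass(frozen=True)
class GeneModel:
    """A gene with its location, strand, biotype and chromosome class."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "."
    biotype: str = DEFAULT_BIOTYPE
    chrom_class: str = ""

    def __post_init__(self):
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.chrom_class:
            object.__setattr__(
                self, "chrom_class", classify_chrom(self.interval.chrom)
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and book-ended intervals, per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


@dataclass
class DomainSet:
    """One flavor of repressive-domain call (LAD, Null, Black, or custom).

    Intervals are merged and sorted on construction, so the stored set is
    non-overlapping by invariant.
    """

    name: str
    intervals: list[GenomicInterval]
    source: str = ""

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]

    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)


@dataclass
class GeneDomainAssignment:
    """Genes fully contained in some interval of one domain set."""

    domain_name: str
    member_gene_ids: frozenset
    rule: str = "both-boundaries-inside"


@dataclass
class ContingencyTable2x2:
    """Counts: rows = in-domain / not-in-domain, cols = X / autosome."""

    a: int  # in-domain, X
    b: int  # in-domain, autosome
    c: int  # not-in-domain, X
    d: int  # not-in-domain, autosome

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")


@dataclass
class DomainPartition:
    """Per-gene domain-membership flags plus Venn-cell accounting.

    ``flags`` is a boolean DataFrame indexed by gene_id with one column per
    domain flavor plus the derived ``repressive_overlap`` (member of every
    flavor) and ``non_repressive`` (member of none) classes. ``venn`` maps
    each membership combination (e.g. ``"LAD&Black"``, ``"none"``) to its
    gene count.
    """

    flags: pd.DataFrame
    venn: dict[str, int] = field(default_factory=dict)

    @property
    def domain_names(self) -> list[str]:
        return [
            c
            for c in self.flags.columns
            if c not in ("repressive_overlap", "non_repressive")
        ]

    def gene_ids(self, column: str) -> set[str]:
        return set(self.flags.index[self.flags[column]])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_gene_models(
    path,
    format: str = "tsv",
    x_names: Sequence[str] = DEFAULT_X_NAMES,
    default_biotype: str = DEFAULT_BIOTYPE,
) -> list[GeneModel]:
    """Read gene models from GFF3, BED12, or a plain gene TSV.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open on
    read. Duplicate gene ids raise a validation error.
    """
    path = Path(path)
    if format == "gff3":
        genes = _read_gff3(path, x_names, default_biotype)
    elif format == "bed12":
        genes = _read_bed12(path, x_names, default_biotype)
    elif format == "tsv":
        genes = _read_gene_tsv(path, x_names)
    else:
        raise ValueError(f"unknown gene-model format: {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().strip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path: Path, x_names, default_biotype) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            attributes = _parse_gff3_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("gene_id")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: gene record without ID")
            biotype = (
                attributes.get("biotype")
                or attributes.get("gene_biotype")
                or default_biotype
            )
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    # GFF3 is 1-based closed; internal convention is
                    # 0-based half-open.
                    interval=GenomicInterval(chrom, start_i - 1, end_i),
                    strand=strand if strand in "+-" else ".",
                    biotype=biotype,
                    chrom_class=classify_chrom(chrom, x_names),
                )
            )
    return genes


def _read_bed12(path: Path, x_names, default_biotype) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                iv = GenomicInterval(chrom, int(start), int(end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad BED record") from exc
            genes.append(
                GeneModel(
                    gene_id=name,
                    interval=iv,
                    strand=strand,
                    biotype=default_biotype,
                    chrom_class=classify_chrom(chrom, x_names),
                )
            )
    return genes


def _read_gene_tsv(path: Path, x_names) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                strand=getattr(row, "strand", "."),
                biotype=getattr(row, "biotype", DEFAULT_BIOTYPE),
                chrom_class=classify_chrom(row.chrom, x_names),
            )
        )
    return genes


def write_gene_tsv(genes: Sequence[GeneModel], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "biotype": [g.biotype for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_domain_bed(path, name: str, source: str = "") -> DomainSet:
    """Read a BED3(+) file into a merged DomainSet."""
    intervals = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad BED record") from exc
    return DomainSet(name=name, intervals=intervals, source=source or str(path))


def write_domain_bed(domains: DomainSet, path) -> None:
    with open(path, "w") as fh:
        for iv in domains.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{domains.name}\n")


# ---------------------------------------------------------------------------
# Assignment and accounting
# ---------------------------------------------------------------------------


def assign_genes_to_domains(
    genes: Iterable[GeneModel], domains: DomainSet
) -> GeneDomainAssignment:
    """Genes whose full interval is contained in one merged domain interval."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in domains.intervals}:
        ivs = domains.on_chrom(chrom)
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    members = set()
    for gene in genes:
        arrs = by_chrom.get(gene.chrom)
        if arrs is None:
            continue
        starts, ends = arrs
        i = int(np.searchsorted(starts, gene.start, side="right")) - 1
        if i >= 0 and ends[i] >= gene.end:
            members.add(gene.gene_id)
    return GeneDomainAssignment(
        domain_name=domains.name, member_gene_ids=frozenset(members)
    )


def domain_overlap_partition(
    assignments: Sequence[GeneDomainAssignment], genes: Iterable[GeneModel]
) -> DomainPartition:
    """Membership flags per flavor, derived overlap classes, Venn counts.

    ``repressive_overlap`` marks genes that belong to every supplied domain
    flavor; ``non_repressive`` marks genes belonging to none.
    """
    if not assignments:
        raise ValueError("need at least one assignment")
    gene_ids = [g.gene_id for g in genes]
    universe = set(gene_ids)
    flags = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for asg in assignments:
        stray = asg.member_gene_ids - universe
        if stray:
            raise ValueError(
                f"assignment {asg.domain_name!r} refers to genes outside the "
                f"gene set, e.g. {sorted(stray)[:3]}"
            )
        flags[asg.domain_name] = flags.index.isin(asg.member_gene_ids)
    names = [a.domain_name for a in assignments]
    flags["repressive_overlap"] = flags[names].all(axis=1)
    flags["non_repressive"] = ~flags[names].any(axis=1)
    venn: dict[str, int] = {}
    member_matrix = flags[names].to_numpy()
    for combo in range(2 ** len(names)):
        included = [names[i] for i in range(len(names)) if combo >> i & 1]
        mask = np.ones(len(flags), dtype=bool)
        for i, nm in enumerate(names):
            want = bool(combo >> i & 1)
            mask &= member_matrix[:, i] == want
        key = "&".join(included) if included else "none"
        venn[key] = int(mask.sum())
    return DomainPartition(flags=flags, venn=venn)


def chromosome_enrichment(
    assignment: GeneDomainAssignment,
    genes: Iterable[GeneModel],
    biotype_filter: bool = True,
    biotypes: Sequence[str] = (DEFAULT_BIOTYPE,),
) -> tuple[ContingencyTable2x2, float, float]:
    """X-vs-autosome enrichment of domain membership (Fisher's exact test).

    Returns ``(table, odds_ratio, two_sided_p)``. By default only genes
    with a protein-coding polyA+ biotype are counted; ``biotype_filter``
    disables the filter. A zero-margin table leaves the odds ratio
    undefined (NaN) with p = 1.
    """
    counted = [
        g for g in genes if not biotype_filter or g.biotype in set(biotypes)
    ]
    members = assignment.member_gene_ids
    a = sum(1 for g in counted if g.gene_id in members and g.chrom_class == "X")
    b = sum(1 for g in counted if g.gene_id in members and g.chrom_class != "X")
    c = sum(1 for g in counted if g.gene_id not in members and g.chrom_class == "X")
    d = sum(1 for g in counted if g.gene_id not in members and g.chrom_class != "X")
    table = ContingencyTable2x2(a, b, c, d)
    odds_ratio, p = resampling.fisher_exact_2x2(table)
    return table, odds_ratio, p
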