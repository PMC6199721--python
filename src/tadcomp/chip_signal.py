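"""Gene-body summarization of windowed ChIP signal and class comparisons.

Tracks arrive pre-normalized as non-overlapping scored windows (e.g.
smoothed log ChIP/input "M values" on 25-bp windows). The per-gene summary
is the median score of all windows overlapping the gene body by at least
one base; genes with no overlapping window are reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import resampling
from .expression_metrics import class_expression_summary
from .genome_domains import GeneModel

__all__ = [
    "SignalTrack",
    "read_signal_track",
    "summarize_gene_signal",
    "class_signal_comparison",
    "sex_difference_by_class",
    "sex_difference_permutation_test",
]


@dataclass
class SignalTrack:
    """Windowed ChIP scores: columns chrom, start, end, score.

    Windows must be non-overlapping within a chromosome; they are sorted
    on construction.
    """

    windows: pd.DataFrame

    def __post_init__(self):
        required = {"chrom", "start", "end", "score"}
        missing = required - set(self.windows.columns)
        if missing:
            raise ValueError(f"track missing columns: {sorted(missing)}")
        self.windows = (
            self.windows.sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )
        for chrom, grp in self.windows.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping windows on {chrom}")

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)


def read_signal_track(path) -> SignalTrack:
    """Read a BED-like 4-column TSV (chrom, start, end, score)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "score"],
        comment="#",
        dtype={"chrom": str},
        float_precision="round_trip",
    )
    if df.columns.size and isinstance(df.iloc[0]["start"], str):
        raise ValueError(f"{path}: non-numeric coordinates")
    return SignalTrack(windows=df)


def summarize_gene_signal(
    track: SignalTrack,
    genes: Iterable[GeneModel],
    stat: str = "median",
) -> pd.DataFrame:
    """Per-gene summary of window scores over the gene body.

    Any window overlapping the gene interval by >= 1 base contributes.
    Returns a DataFrame indexed by gene_id with columns ``summary`` (NaN
    when no window overlaps) and ``n_windows``.
    """
    if stat != "median":
        raise ValueError(f"unsupported stat: {stat!r}")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in track.windows.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["score"].to_numpy(float),
        )
    ids, summaries, counts = [], [], []
    for gene in genes:
        ids.append(gene.gene_id)
        arrs = by_chrom.get(gene.chrom)
        if arrs is None:
            summaries.append(np.nan)
            counts.append(0)
            continue
        starts, ends, scores = arrs
        # Windows are sorted and non-overlapping, so the overlapping set
        # is the contiguous run [lo, hi).
        lo = int(np.searchsorted(ends, gene.start, side="right"))
        hi = int(np.searchsorted(starts, gene.end, side="left"))
        if hi > lo:
            summaries.append(float(np.median(scores[lo:hi])))
            counts.append(hi - lo)
        else:
            summaries.append(np.nan)
            counts.append(0)
    return pd.DataFrame(
        {"summary": summaries, "n_windows": counts},
        index=pd.Index(ids, name="gene_id"),
    )


def class_signal_comparison(
    gene_signal: pd.DataFrame,
    classes: Mapping[str, set[str]],
    compare: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Boxplot statistics of gene-body signal per class, plus a MW p.

    ``compare`` names the two classes tested against each other (two-sided
    Mann-Whitney U); defaults to the first two keys of ``classes``.
    """
    values = gene_signal["summary"].dropna()
    summary = class_expression_summary(values, classes)
    names = list(classes) if compare is None else list(compare)
    x = values.reindex(sorted(classes[names[0]])).dropna().to_numpy()
    y = values.reindex(sorted(classes[names[1]])).dropna().to_numpy()
    if x.size == 0 or y.size == 0:
        return summary, float("nan")
    _, p = resampling.mann_whitney_u(x, y, "two-sided")
    return summary, float(p)


def sex_difference_by_class(
    male_signal: pd.DataFrame,
    female_signal: pd.DataFrame,
    classes: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-gene (male - female) gene-body signal, labelled by class.

    Genes missing a summary in either sex are dropped; genes falling in no
    supplied class are omitted. Raises when the two signals share no
    scored genes.
    """
    male = male_signal["summary"]
    female = female_signal["summary"]
    shared = male.index.intersection(female.index)
    diffs = (male.reindex(shared) - female.reindex(shared)).dropna()
    if diffs.empty:
        raise ValueError("no genes with signal in both sexes")
    rows = []
    for name, ids in classes.items():
        for gid in sorted(ids):
            if gid in diffs.index:
                rows.append({"gene_id": gid, "difference": diffs[gid], "class": name})
    return pd.DataFrame(rows)


def sex_difference_permutation_test(
    differences: pd.DataFrame,
    n_perm: int = 2000,
    seed: int = 0,
    tail: str = "greater",
    repressive_label: str = "repressive",
    non_repressive_label: str = "non_repressive",
) -> resampling.PermutationResult:
    """Is the male-excess signal smaller in repressive domains?

    The statistic is ``median(diff | non-repressive) - median(diff |
    repressive)``; a positive value means the male-specific enrichment is
    concentrated outside repressive domains. The null shuffles class
    labels over genes; ``tail="greater"`` asks whether the observed
    concentration exceeds chance.
    """
    sub = differences[
        differences["class"].isin([repressive_label, non_repressive_label])
    ]
    values = sub["difference"].to_numpy(float)
    # label_permutation_test orders groups by sorted unique label; map the
    # non-repressive class to the lexically first level so the statistic
    # sign convention (positive = larger non-repressive median) holds.
    labels = np.where(sub["class"].to_numpy() == non_repressive_label, "a_nonrep", "b_rep")
    return resampling.label_permutation_test(
        values,
        labels,
        statistic="diff_of_medians",
        n_perm=n_perm,
        seed=seed,
        tail=tail,
    )
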