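"""Expression cutoffs, expressed-gene filtering, and compensation ratios.

Three cutoff estimators separate "low but real" expression from noise, the
central measurement problem when asking whether genes inside repressive
chromatin domains are dosage compensated rather than simply off:

* ``intergenic_percentile`` — a high percentile (default 99th) of FPKM
  signal measured over intergenic windows (sequencing platforms);
* ``control_probe_percentile`` — the same percentile of non-target control
  probe intensities (array platforms);
* ``em_mixture`` — a two-component Gaussian mixture fitted by EM to a
  bimodal normalized-intensity distribution; the cutoff is a high quantile
  (default 99.9th) of the lower-mean (background) component.

Downstream operations compare expression by domain class, form per-gene
male/female log2 ratios (a compensated one-dose gene sits near 0, an
uncompensated one near -1), build median-matched comparison sets by
trimming highly expressed genes, and contrast knockdown responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from . import resampling

__all__ = [
    "ExpressionTable",
    "CutoffEstimate",
    "MixtureFit",
    "TrimResult",
    "percentile_cutoff",
    "em_background_cutoff",
    "filter_expressed",
    "class_expression_summary",
    "mf_log2_ratio",
    "match_medians_by_trimming",
    "knockdown_log2fc",
    "class_response_comparison",
]

SIGMA_FLOOR = 1e-3


@dataclass
class ExpressionTable:
    """Gene x sample expression with per-sample metadata.

    ``values`` is genes (rows) x samples (columns); units are FPKM for
    sequencing samples and normalized (log-scale) intensity for arrays.
    ``samples`` is indexed by sample id with columns ``sex`` (F/M),
    ``source``, ``condition``, ``platform`` (rnaseq/array).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples lack metadata: {sorted(missing)}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()][:3]
            raise ValueError(f"duplicate gene ids: {list(dupes)}")

    def select(self, **criteria) -> list[str]:
        """Sample ids whose metadata match all ``column=value`` criteria."""
        mask = pd.Series(True, index=self.samples.index)
        for col, value in criteria.items():
            mask &= self.samples[col] == value
        return [s for s in self.values.columns if mask.get(s, False)]

    def to_tsv(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "ExpressionTable":
        values = pd.read_csv(
            values_path, sep="\t", index_col="gene_id", float_precision="round_trip"
        )
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(values=values, samples=samples)


@dataclass
class CutoffEstimate:
    method: str
    cutoff: float
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


@dataclass
class MixtureFit:
    """A k=2 Gaussian mixture fitted by EM."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    background_index: int
    detail: dict = field(default_factory=dict)


def percentile_cutoff(values: Sequence[float], q: float) -> CutoffEstimate:
    """Percentile-of-background cutoff.

    Linear interpolation between order statistics at rank
    ``1 + (n - 1) * q / 100``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile_cutoff requires non-empty values")
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    cutoff = float(np.percentile(values, q))
    return CutoffEstimate(
        method="intergenic_percentile",
        cutoff=cutoff,
        detail={"q": q, "n": int(values.size)},
    )


def _mixture_loglik(x, w, mu, sd) -> tuple[float, np.ndarray]:
    logp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
    per_obs = logsumexp(logp, axis=0)
    resp = np.exp(logp - per_obs[None, :])
    return float(per_obs.sum()), resp


def em_background_cutoff(
    values: Sequence[float],
    q: float = 99.9,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
) -> tuple[MixtureFit, CutoffEstimate]:
    """Fit a 2-Gaussian mixture by EM; cutoff from the background component.

    The background is the lower-mean component; the cutoff is
    ``mu_bg + z_{q/100} * sigma_bg`` (z ~ 3.0902 for q = 99.9). EM starts
    from a split at the sample median and stops when the log-likelihood
    gain falls below ``tol`` (the gain is non-decreasing by construction
    and asserted each step). Degenerate fits — a vanishing component
    weight, a standard deviation pinned to the floor, or a likelihood gain
    over a single Gaussian too small to support a second mode — are
    flagged non-converged, with the cutoff still reported. ``seed`` is
    accepted for interface stability; the default initialization is
    deterministic and uses no randomness.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 50:
        raise ValueError("em_background_cutoff requires n >= 50")
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum([lo.std(), hi.std()], SIGMA_FLOOR)
    w = np.array([0.5, 0.5])
    loglik, resp = _mixture_loglik(x, w, mu, sd)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = resp @ x / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.maximum(np.sqrt(var), SIGMA_FLOOR)
        new_loglik, resp = _mixture_loglik(x, w, mu, sd)
        if new_loglik < loglik - 1e-6 * max(1.0, abs(loglik)):
            raise AssertionError(
                f"EM log-likelihood decreased: {loglik} -> {new_loglik}"
            )
        delta, loglik = new_loglik - loglik, new_loglik
        if abs(delta) < tol:
            converged = True
            break
    bg = int(np.argmin(mu))
    # Compare against a single-Gaussian fit: on unimodal data the second
    # component buys almost no likelihood and the fit is labelled degenerate.
    single_ll = float(norm.logpdf(x, x.mean(), max(x.std(), SIGMA_FLOOR)).sum())
    gain_per_obs = (loglik - single_ll) / x.size
    reasons = []
    if w.min() < 0.01:
        reasons.append("component weight below 0.01")
    if (sd <= SIGMA_FLOOR).any():
        reasons.append("sigma collapsed to floor")
    if gain_per_obs < 0.005:
        reasons.append("no support for a second mode")
    degenerate = bool(reasons)
    fit = MixtureFit(
        k=2,
        weights=w,
        means=mu,
        sds=sd,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged and not degenerate,
        background_index=bg,
        detail={
            "degenerate": degenerate,
            "degenerate_reasons": reasons,
            "loglik_gain_per_obs_vs_single": gain_per_obs,
        },
    )
    z = float(norm.ppf(q / 100.0))
    cutoff = CutoffEstimate(
        method="em_mixture",
        cutoff=float(mu[bg] + z * sd[bg]),
        detail={
            "q": q,
            "z": z,
            "background_mean": float(mu[bg]),
            "background_sd": float(sd[bg]),
            "warning": "degenerate fit" if degenerate else "",
        },
    )
    return fit, cutoff


def filter_expressed(
    table: ExpressionTable,
    cutoff: CutoffEstimate | float,
    scope: Sequence[str] | None = None,
) -> tuple[set[str], pd.Series]:
    """Genes strictly above the cutoff in at least one scope sample.

    Returns ``(kept_gene_ids, per_gene_max)`` where the second element is
    the per-gene maximum over the scope (useful for reporting). A gene
    exactly at the cutoff is excluded (strict inequality).
    """
    threshold = cutoff.cutoff if isinstance(cutoff, CutoffEstimate) else float(cutoff)
    columns = list(table.values.columns) if scope is None else list(scope)
    missing = set(columns) - set(table.values.columns)
    if missing:
        raise ValueError(f"scope samples not in table: {sorted(missing)}")
    sub = table.values[columns]
    per_gene_max = sub.max(axis=1)
    kept = set(per_gene_max.index[per_gene_max > threshold])
    return kept, per_gene_max


def class_expression_summary(
    values: pd.Series | Mapping[str, float],
    classes: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Boxplot statistics (median, quartiles, whiskers, notch) per class.

    ``values`` maps gene_id -> expression (already filtered to expressed
    genes); ``classes`` maps class name -> gene ids. Whiskers are the most
    extreme observations within 1.5*IQR of the box; the notch half-width
    is ``1.58 * IQR / sqrt(n)`` (the standard 95% CI for a median). Empty
    classes are reported with NaN statistics rather than raising.
    """
    values = pd.Series(values, dtype=float)
    rows = []
    for name, ids in classes.items():
        v = values.reindex(sorted(ids)).dropna().to_numpy()
        if v.size == 0:
            rows.append(
                {"class": name, "n": 0, "median": np.nan, "q1": np.nan,
                 "q3": np.nan, "whisker_low": np.nan, "whisker_high": np.nan,
                 "notch_halfwidth": np.nan}
            )
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_lo = v[v >= q1 - 1.5 * iqr]
        in_hi = v[v <= q3 + 1.5 * iqr]
        rows.append(
            {
                "class": name,
                "n": int(v.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(in_lo.min()),
                "whisker_high": float(in_hi.max()),
                "notch_halfwidth": float(1.58 * iqr / np.sqrt(v.size)),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def mf_log2_ratio(
    table: ExpressionTable,
    male_samples: Sequence[str],
    female_samples: Sequence[str],
    classes: Mapping[str, set[str]],
    expressed: set[str] | None = None,
    reference_class: str | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene log2(male/female) ratios and per-class medians.

    Replicates are aggregated by arithmetic mean per sex before the ratio.
    Genes with a zero (or negative) female mean are dropped and counted.
    When ``reference_class`` is given, each class is additionally compared
    by Mann-Whitney U against the reference class's ratios re-centered on
    zero (so a significant p flags a class whose ratios sit away from the
    compensated baseline).
    """
    male = table.values[list(male_samples)].mean(axis=1)
    female = table.values[list(female_samples)].mean(axis=1)
    keep = female > 0
    n_dropped = int((~keep).sum())
    ratios = np.log2(male[keep] / female[keep])
    if expressed is not None:
        ratios = ratios[ratios.index.isin(expressed)]
    ref_values = None
    if reference_class is not None:
        ref = ratios.reindex(sorted(classes[reference_class])).dropna()
        ref_values = (ref - ref.median()).to_numpy()
    rows = []
    for name, ids in classes.items():
        v = ratios.reindex(sorted(ids)).dropna().to_numpy()
        median = float(np.median(v)) if v.size else np.nan
        p = np.nan
        if ref_values is not None and v.size and ref_values.size:
            _, p = resampling.mann_whitney_u(v, ref_values, "two-sided")
        rows.append(
            {"class": name, "n": int(v.size), "median_log2_mf": median,
             "p_vs_reference": p, "n_dropped_zero_female": n_dropped}
        )
    return ratios, pd.DataFrame(rows).set_index("class")


@dataclass
class TrimResult:
    """Outcome of median matching by trimming."""

    kept_gene_ids: list[str]
    removed_gene_ids: list[str]  # in removal order
    target_median: float
    reference_median: float


def match_medians_by_trimming(
    reference_values: Sequence[float],
    target: Mapping[str, float] | pd.Series,
) -> TrimResult:
    """Trim the highest-expressed target genes until medians match.

    Iteratively removes the current maximum-value target gene until the
    target median is at or below the reference median, returning the first
    (largest) set satisfying the condition. Ties on value are broken by
    gene_id (lexicographically last removed first) so removal order is
    deterministic. A target whose median already satisfies the condition
    is returned unchanged. Raises if the condition cannot be met before
    the target is exhausted (fewer than 2 genes left).
    """
    reference_values = np.asarray(list(reference_values), dtype=float)
    if reference_values.size == 0:
        raise ValueError("reference must be non-empty")
    target = pd.Series(dict(target), dtype=float)
    if target.size == 0:
        raise ValueError("target must be non-empty")
    ref_median = float(np.median(reference_values))
    # Sort ascending by (value, gene_id): trimming pops from the end.
    order = sorted(target.index, key=lambda g: (target[g], g))
    values = [float(target[g]) for g in order]
    removed: list[str] = []
    while np.median(values) > ref_median:
        if len(values) <= 1:
            raise ValueError(
                "median matching infeasible: target exhausted before its "
                "median reached the reference median"
            )
        removed.append(order.pop())
        values.pop()
    return TrimResult(
        kept_gene_ids=order,
        removed_gene_ids=removed,
        target_median=float(np.median(values)),
        reference_median=ref_median,
    )


def knockdown_log2fc(
    control: pd.DataFrame,
    treatment: pd.DataFrame,
    platform: str,
) -> pd.Series:
    """Per-gene log2 fold change of treatment over control.

    A documented plain normalization stands in for moderated model fits:
    for ``platform="rnaseq"`` the columns are read counts, scaled to
    counts-per-million with a +0.5 offset before the log2 ratio of
    replicate-mean CPMs; for ``platform="array"`` the columns are already
    log-scale intensities and replicate means are differenced.
    """
    if set(control.index) != set(treatment.index):
        diff = set(control.index) ^ set(treatment.index)
        raise ValueError(
            f"control/treatment gene sets differ, e.g. {sorted(diff)[:5]}"
        )
    treatment = treatment.reindex(control.index)
    if platform == "rnaseq":
        lib_c = control.sum(axis=0)
        lib_t = treatment.sum(axis=0)
        if (lib_c <= 0).any() or (lib_t <= 0).any():
            raise ValueError("library sizes must be positive")
        cpm_c = (control / lib_c) * 1e6
        cpm_t = (treatment / lib_t) * 1e6
        return np.log2(cpm_t.mean(axis=1) + 0.5) - np.log2(cpm_c.mean(axis=1) + 0.5)
    if platform == "array":
        return treatment.mean(axis=1) - control.mean(axis=1)
    raise ValueError(f"unknown platform: {platform!r}")


def class_response_comparison(
    log2fc: pd.Series,
    repressive_ids: set[str],
    non_repressive_ids: set[str],
) -> dict:
    """Contrast knockdown responses of repressive vs non-repressive genes.

    Returns medians, sizes, and a two-sided Mann-Whitney p. Run this
    separately per chromosome class (X vs autosomes) by pre-restricting
    the id sets.
    """
    rep = log2fc.reindex(sorted(repressive_ids)).dropna().to_numpy()
    nonrep = log2fc.reindex(sorted(non_repressive_ids)).dropna().to_numpy()
    if rep.size == 0 or nonrep.size == 0:
        raise ValueError("both classes must be non-empty among scored genes")
    _, p = resampling.mann_whitney_u(rep, nonrep, "two-sided")
    return {
        "n_repressive": int(rep.size),
        "n_non_repressive": int(nonrep.size),
        "median_repressive": float(np.median(rep)),
        "median_non_repressive": float(np.median(nonrep)),
        "p_two_sided": float(p),
    }
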