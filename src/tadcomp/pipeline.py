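"""Full-analysis orchestration: from a fixture bundle to a results manifest.

The stage order follows the scientific argument: assign genes to repressive
domains, establish expression cutoffs and expressed-gene sets, compare
class-wise expression and male/female ratios, summarize ChIP signal and
test the sex difference, scan for recognition-element motifs and test
entry-site depletion by domain shuffling, re-compare ChIP on
median-matched expression sets, and finally contrast knockdown responses.

Each stage writes one TSV analog of a figure/table; every statistic, with
the seed and parameters that produced it, lands in ``manifest.json``.
Manifests are byte-identical across runs with identical config and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip_signal, expression_metrics, motif_mre, resampling
from .genome_domains import (
    DEFAULT_BIOTYPE,
    assign_genes_to_domains,
    chromosome_enrichment,
    domain_overlap_partition,
)
from .synthetic_data import read_fixture_bundle

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("tadcomp.pipeline")


@dataclass
class RunConfig:
    """Parameters of one full analysis run."""

    bundle_dir: str
    out_dir: str
    seed: int = 0
    n_shuffles: int = 2000
    n_perm: int = 2000
    e_threshold: float = 1.0e-5
    percentile_q: float = 99.0
    em_q: float = 99.9
    biotype_filter: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if not Path(self.bundle_dir).is_dir():
            raise FileNotFoundError(f"bundle_dir not found: {self.bundle_dir}")
        for name, value in (("n_shuffles", self.n_shuffles), ("n_perm", self.n_perm)):
            if value < 1:
                raise ValueError(f"{name} must be >= 1")


def _coding(genes):
    return [g for g in genes if g.biotype == DEFAULT_BIOTYPE]


def _x_classes(partition, genes, chrom_class: str) -> dict[str, set[str]]:
    """Class -> gene ids, restricted to one chromosome class (coding only)."""
    ids = {g.gene_id for g in _coding(genes) if g.chrom_class == chrom_class}
    classes = {}
    for column in partition.flags.columns:
        classes[column] = partition.gene_ids(column) & ids
    return classes


def run_full_analysis(config: RunConfig) -> tuple[Path, dict]:
    """Execute every stage; returns ``(out_dir, manifest)``.

    Stages whose optional inputs are missing from the bundle (expression,
    tracks) are skipped with a logged warning; missing required inputs
    (genes, domains, sequence) abort via the bundle reader.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    bundle = read_fixture_bundle(config.bundle_dir)
    manifest: dict = {
        "parameters": {
            "seed": config.seed,
            "n_shuffles": config.n_shuffles,
            "n_perm": config.n_perm,
            "e_threshold": config.e_threshold,
            "percentile_q": config.percentile_q,
            "em_q": config.em_q,
            "bundle_config_hash": bundle.manifest.get("config_hash", ""),
            "bundle_seed": bundle.manifest.get("seed"),
        }
    }
    genes = bundle.genes

    # --- stage 1: domain assignment, Venn accounting, enrichment ----------
    log.info("stage=assign n_genes=%d", len(genes))
    assignments = [
        assign_genes_to_domains(genes, dset)
        for _, dset in sorted(bundle.domain_sets.items())
    ]
    partition = domain_overlap_partition(assignments, genes)
    partition.flags.to_csv(out / "assignment.tsv", sep="\t")
    pd.Series(partition.venn, name="n_genes").rename_axis("combination").to_csv(
        out / "venn.tsv", sep="\t"
    )
    manifest["venn"] = partition.venn
    enrich_rows = []
    manifest["enrichment"] = {}
    for asg in assignments:
        table, odds, p = chromosome_enrichment(
            asg, genes, biotype_filter=config.biotype_filter
        )
        enrich_rows.append(
            {
                "domain": asg.domain_name,
                "in_domain_X": table.a,
                "in_domain_autosome": table.b,
                "out_domain_X": table.c,
                "out_domain_autosome": table.d,
                "odds_ratio": odds,
                "p_two_sided": p,
            }
        )
        manifest["enrichment"][asg.domain_name] = {
            "odds_ratio": odds,
            "p_two_sided": p,
            "figure_analog": "fig1b",
        }
    pd.DataFrame(enrich_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    if bundle.expression is None:
        log.warning("stage=expression skipped: no expression in bundle")
        _write_manifest(out, manifest, t0)
        return out, manifest

    table = bundle.expression

    # --- stage 2: cutoffs and expressed-gene sets -------------------------
    cutoffs: dict = {}
    if "intergenic" in bundle.aux:
        est = expression_metrics.percentile_cutoff(
            bundle.aux["intergenic"], config.percentile_q
        )
        cutoffs["rnaseq"] = est
    if "control_probes" in bundle.aux:
        est = expression_metrics.percentile_cutoff(
            bundle.aux["control_probes"], config.percentile_q
        )
        est.method = "control_probe_percentile"
        cutoffs["array"] = est
    array_controls = table.select(platform="array", condition="control")
    em_record = {}
    if array_controls:
        pooled = table.values[array_controls].to_numpy().ravel()
        fit, em_cut = expression_metrics.em_background_cutoff(pooled, q=config.em_q)
        cutoffs["em_array"] = em_cut
        em_record = {
            "cutoff": em_cut.cutoff,
            "background_mean": em_cut.detail["background_mean"],
            "background_sd": em_cut.detail["background_sd"],
            "converged": fit.converged,
            "n_iter": fit.n_iter,
        }
    manifest["cutoffs"] = {
        name: {"method": est.method, "cutoff": est.cutoff, "q": est.detail.get("q")}
        for name, est in cutoffs.items()
    }
    if em_record:
        manifest["cutoffs"]["em_array"].update(em_record)

    groups = {
        "kc_F_rnaseq": table.select(sex="F", platform="rnaseq", condition="control"),
        "s2_M_rnaseq": table.select(sex="M", platform="rnaseq", condition="control"),
        "sg_F_array": table.select(sex="F", source="sg", condition="control"),
        "sg_M_array": table.select(sex="M", source="sg", condition="control"),
    }
    expressed: dict[str, set] = {}
    for name, cols in groups.items():
        if not cols:
            continue
        platform = "array" if name.endswith("array") else "rnaseq"
        if platform not in cutoffs:
            continue
        expressed[name], _ = expression_metrics.filter_expressed(
            table, cutoffs[platform], scope=cols
        )

    classes_x = _x_classes(partition, genes, "X")
    classes_auto = _x_classes(partition, genes, "autosome")

    # --- stage 3: Table-1-style accounting and class expression ----------
    rows = []
    for group, kept in expressed.items():
        cols = groups[group]
        means = table.values[cols].mean(axis=1)
        for chrom_class, classes in (("X", classes_x), ("autosome", classes_auto)):
            for cname, ids in classes.items():
                exp_ids = sorted(ids & kept)
                med = float(means.reindex(exp_ids).median()) if exp_ids else np.nan
                rows.append(
                    {
                        "group": group,
                        "class": cname,
                        "chrom_class": chrom_class,
                        "n_genes": len(ids),
                        "n_expressed": len(exp_ids),
                        "median_expression": med,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "table1.tsv", sep="\t", index=False)

    male_rna = groups["s2_M_rnaseq"]
    female_rna = groups["kc_F_rnaseq"]
    summaries = []
    if male_rna and "s2_M_rnaseq" in expressed:
        log_vals = np.log2(table.values[male_rna].mean(axis=1))
        log_vals = log_vals[log_vals.index.isin(expressed["s2_M_rnaseq"])]
        summary = expression_metrics.class_expression_summary(log_vals, classes_x)
        summary.insert(0, "group", "s2_M_rnaseq_log2fpkm")
        summaries.append(summary)
    if summaries:
        pd.concat(summaries).to_csv(out / "class_expression.tsv", sep="\t")

    # --- stage 4: male/female compensation ratios -------------------------
    if male_rna and female_rna and expressed:
        both = expressed.get("s2_M_rnaseq", set()) & expressed.get("kc_F_rnaseq", set())
        ratios, per_class = expression_metrics.mf_log2_ratio(
            table,
            male_rna,
            female_rna,
            classes_x,
            expressed=both,
            reference_class="non_repressive",
        )
        ratios.rename("log2_mf").to_csv(out / "mf_ratios.tsv", sep="\t")
        per_class.to_csv(out / "mf_ratio_classes.tsv", sep="\t")
        manifest["mf_ratios"] = {
            cname: {
                "median_log2_mf": _nan_to_none(row["median_log2_mf"]),
                "n": int(row["n"]),
                "p_vs_reference": _nan_to_none(row["p_vs_reference"]),
                "figure_analog": "fig1l",
            }
            for cname, row in per_class.iterrows()
        }

    # --- stage 5: ChIP summarization, class and sex-difference tests -----
    gene_signals: dict = {}
    for key, track in sorted(bundle.tracks.items()):
        gene_signals[key] = chip_signal.summarize_gene_signal(track, genes)
    if gene_signals:
        manifest["chip"] = {}
        chip_rows = []
        for (target, sex, condition), signal in gene_signals.items():
            if condition != "control":
                continue
            summary, p = chip_signal.class_signal_comparison(
                signal,
                classes_x,
                compare=("repressive_overlap", "non_repressive"),
            )
            summary.insert(0, "target", target)
            summary.insert(1, "sex", sex)
            chip_rows.append(summary)
            manifest["chip"][f"{target}_{sex}"] = {
                "p_repressive_vs_non": _nan_to_none(p),
                "figure_analog": "fig2a-o",
            }
        if chip_rows:
            pd.concat(chip_rows).to_csv(out / "chip_class.tsv", sep="\t")
        manifest["sex_difference"] = {}
        sexdiff_rows = []
        for target in sorted({t for t, _, c in gene_signals if c == "control"}):
            male = gene_signals.get((target, "M", "control"))
            female = gene_signals.get((target, "F", "control"))
            if male is None or female is None:
                continue
            diffs = chip_signal.sex_difference_by_class(
                male,
                female,
                {
                    "repressive": classes_x["repressive_overlap"],
                    "non_repressive": classes_x["non_repressive"],
                },
            )
            if diffs.empty or diffs["class"].nunique() < 2:
                log.warning(
                    "stage=sex_difference skipped for %s: a class is empty", target
                )
                continue
            result = chip_signal.sex_difference_permutation_test(
                diffs, n_perm=config.n_perm, seed=config.seed + 101, tail="greater"
            )
            sexdiff_rows.append({"target": target, **result.to_record()})
            manifest["sex_difference"][target] = {
                **result.to_record(),
                "figure_analog": "fig2p-q",
            }
        if sexdiff_rows:
            pd.DataFrame(sexdiff_rows).to_csv(
                out / "sex_difference.tsv", sep="\t", index=False
            )

    # --- stage 6: motif scan and entry-site shuffle tests -----------------
    x_chrom = next(
        (c for c in bundle.sequences if any(g.chrom == c and g.chrom_class == "X"
                                            for g in genes)),
        None,
    )
    if x_chrom is not None and bundle.training_sites:
        pwm = motif_mre.build_pwm(bundle.training_sites)
        hits = motif_mre.scan_sequence(
            pwm,
            bundle.sequences[x_chrom],
            chrom=x_chrom,
            e_threshold=config.e_threshold,
        )
        motif_mre.write_hits_bed(hits, pwm.width, out / "mre_hits.bed")
        mre_intervals = motif_mre.hits_to_intervals(hits, pwm.width)
        manifest["motif"] = {
            "n_hits_x": len(hits),
            "pwm_width": pwm.width,
            "e_threshold": config.e_threshold,
        }
        x_len = len(bundle.sequences[x_chrom])
        manifest["shuffle"] = {}
        shuffle_rows = []
        for i, (name, dset) in enumerate(sorted(bundle.domain_sets.items())):
            domains_x = dset.on_chrom(x_chrom)
            for j, (feat_name, feats, analog) in enumerate(
                (
                    ("MRE", mre_intervals, "fig2r"),
                    ("CES", bundle.entry_sites, "fig2s"),
                )
            ):
                res = resampling.shuffle_overlap_test(
                    domains_x,
                    feats,
                    chrom_length=x_len,
                    n_shuffles=config.n_shuffles,
                    seed=config.seed + 200 + 10 * i + j,
                )
                shuffle_rows.append(
                    {"domain": name, "features": feat_name, **res.to_record()}
                )
                manifest["shuffle"][f"{name}_{feat_name}"] = {
                    **res.to_record(),
                    "figure_analog": analog,
                }
        pd.DataFrame(shuffle_rows).to_csv(
            out / "shuffle_tests.tsv", sep="\t", index=False
        )

    # --- stage 7: median-matched ChIP comparison --------------------------
    mof_male = gene_signals.get(("MOF", "M", "control"))
    if (
        mof_male is not None
        and male_rna
        and "s2_M_rnaseq" in expressed
        and classes_x["repressive_overlap"]
    ):
        male_means = table.values[male_rna].mean(axis=1)
        exp = expressed["s2_M_rnaseq"]
        rep_ids = sorted(classes_x["repressive_overlap"] & exp)
        nonrep_ids = sorted(classes_x["non_repressive"] & exp)
        ref_values = male_means.reindex(rep_ids).dropna()
        target = male_means.reindex(nonrep_ids).dropna()
        try:
            trim = expression_metrics.match_medians_by_trimming(
                ref_values.to_numpy(), target
            )
            matched = set(trim.kept_gene_ids)
            sig = mof_male["summary"]
            rep_sig = sig.reindex(rep_ids).dropna().to_numpy()
            matched_sig = sig.reindex(sorted(matched)).dropna().to_numpy()
            _, p = resampling.mann_whitney_u(rep_sig, matched_sig, "two-sided")
            record = {
                "n_repressive": len(rep_sig),
                "n_matched_non_repressive": len(matched_sig),
                "n_trimmed": len(trim.removed_gene_ids),
                "median_expr_repressive": trim.reference_median,
                "median_expr_matched": trim.target_median,
                "median_mof_repressive": float(np.median(rep_sig)),
                "median_mof_matched": float(np.median(matched_sig)),
                "p_two_sided": p,
                "figure_analog": "fig3b",
            }
            manifest["median_matched"] = record
            pd.DataFrame([record]).to_csv(
                out / "median_matched.tsv", sep="\t", index=False
            )
        except ValueError as exc:
            log.warning("stage=median_match skipped: %s", exc)

    # --- stage 8: knockdown response contrasts ----------------------------
    kd_conditions = sorted(
        set(table.samples["condition"]) - {"control"}
    )
    if kd_conditions and "s2_M_rnaseq" in expressed:
        manifest["knockdown"] = {}
        kd_rows = []
        exp = expressed["s2_M_rnaseq"]
        for condition in kd_conditions:
            kd_cols = table.select(condition=condition)
            meta = table.samples.loc[kd_cols[0]]
            ctrl_cols = table.select(
                condition="control",
                sex=meta["sex"],
                source=meta["source"],
                platform=meta["platform"],
            )
            if not ctrl_cols:
                log.warning("stage=knockdown no matched control for %s", condition)
                continue
            log2fc = expression_metrics.knockdown_log2fc(
                table.values[ctrl_cols], table.values[kd_cols], meta["platform"]
            )
            log2fc = log2fc[log2fc.index.isin(exp)]
            for chrom_class, classes in (("X", classes_x), ("autosome", classes_auto)):
                rep = classes["repressive_overlap"] & exp
                nonrep = classes["non_repressive"] & exp
                if not rep or not nonrep:
                    continue
                contrast = expression_metrics.class_response_comparison(
                    log2fc, rep, nonrep
                )
                record = {
                    "condition": condition,
                    "chrom_class": chrom_class,
                    **contrast,
                    "figure_analog": "fig4a" if chrom_class == "X" else "fig4b",
                }
                if chrom_class == "X":
                    record["msl_factor_estimate"] = float(
                        2.0 ** -contrast["median_non_repressive"]
                    )
                kd_rows.append(record)
                manifest["knockdown"][f"{condition}_{chrom_class}"] = record
        if kd_rows:
            pd.DataFrame(kd_rows).to_csv(out / "knockdown.tsv", sep="\t", index=False)

    _write_manifest(out, manifest, t0)
    return out, manifest


def _nan_to_none(value):
    if value is None:
        return None
    value = float(value)
    return None if np.isnan(value) else value


def _write_manifest(out: Path, manifest: dict, t0: float) -> None:
    log.info("stage=done wall_time=%.1fs", time.time() - t0)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
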