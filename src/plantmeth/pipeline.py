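"""Configuration-driven orchestration of the full analysis.

A run consumes one YAML config naming the inputs (per-tissue replicate call
files, gene/TE annotations, counts matrix, sample sheet, TF list, term map)
and stage parameter blocks, executes the stages in dependency order, and
writes per-stage TSV/BED outputs plus a machine-readable ``summary.json``,
a ``manifest.json`` with SHA-256 checksums of every output, and a plain-text
log with per-stage row counts and filter attrition.  Reruns on identical
inputs produce byte-identical outputs (no timestamps, fixed float formats,
no run-time randomness).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calls as mcalls
from . import dmr as mdmr
from . import dmv as mdmv
from . import expression as mexpr
from . import integrate as mintegrate
from . import metaplot as mmeta
from . import profiles as mprof
from .calls import CONTEXTS

STAGES = ("profiles", "metaplot", "dmr", "dmv", "expr", "integrate")

DEFAULT_PARAMS = {
    "profiles": {
        "window": 500_000,          # genome-overview window (bp)
        "replicate_window": 100_000,
        "error_rate": 0.005,        # methylcytosine binomial call error rate
    },
    "metaplot": {"flank_bp": 2000, "body_bins": 20, "flank_bins": 20},
    "dmr": {
        "bin_size": 100,
        "min_site_coverage": 4,
        "min_sites_per_bin": 3,
        "diff_thresholds": {"CG": 0.4, "CHG": 0.2, "CHH": 0.1},
        "q_threshold": 0.05,
        "flank_bp": 2000,
    },
    "dmv": {
        "bin_size": 1000,
        "max_level": 0.05,
        "min_reads": 5,
        "gene_flank": 1000,
        "mode": "contained",
    },
    "expr": {"fpkm_threshold": 1.0, "min_fold": 4.0, "q_threshold": 0.05},
    "integrate": {"flank_bp": 2000, "q_threshold": 0.05},
}


class PipelineError(RuntimeError):
    pass


def _merged_params(user: dict | None) -> dict:
    out = {}
    user = user or {}
    for stage, defaults in DEFAULT_PARAMS.items():
        block = dict(defaults)
        for k, v in (user.get(stage) or {}).items():
            if isinstance(v, dict) and isinstance(block.get(k), dict):
                merged = dict(block[k])
                merged.update(v)
                block[k] = merged
            else:
                block[k] = v
        out[stage] = block
    return out


@dataclass
class RunConfig:
    calls: dict                      # tissue -> list of call file paths
    genome: str
    genes: str
    tes: str
    counts: str | None = None
    samples: str | None = None
    tf_genes: str | None = None
    term_map: str | None = None
    dialect: str = "methratio"
    tissues: list = field(default_factory=list)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        paths = raw.get("paths", {})

        def _abs(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        calls = {
            tissue: [_abs(p) for p in files]
            for tissue, files in paths.get("calls", {}).items()
        }
        stages = {s: True for s in STAGES}
        stages.update(raw.get("stages", {}))
        return cls(
            calls=calls,
            genome=_abs(paths.get("genome")),
            genes=_abs(paths.get("genes")),
            tes=_abs(paths.get("tes")),
            counts=_abs(paths.get("counts")),
            samples=_abs(paths.get("samples")),
            tf_genes=_abs(paths.get("tf_genes")),
            term_map=_abs(paths.get("term_map")),
            dialect=raw.get("dialect", "methratio"),
            tissues=raw.get("tissues", list(calls)),
            stages=stages,
            params=raw.get("params", {}),
        )

    def validate(self) -> None:
        missing = []
        for tissue, files in self.calls.items():
            for f in files:
                if not Path(f).exists():
                    missing.append(f)
        for p in (self.genome, self.genes, self.tes, self.counts, self.samples,
                  self.tf_genes, self.term_map):
            if p is not None and not Path(p).exists():
                missing.append(p)
        if missing:
            raise PipelineError(f"missing inputs: {missing}")
        if not self.calls:
            raise PipelineError("no call files configured")


def _comparisons(tissues: list) -> list[tuple[str, str]]:
    """Ordered tissue pairs; the later tissue in the configured order is the
    left member (A) of each comparison, e.g. root vs leaf."""
    return [(b, a) for a, b in combinations(tissues, 2)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    def __init__(self, config: RunConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log_lines: list[str] = []
        self.summary: dict = {}
        self.stage_status: dict = {}

    def log(self, msg: str) -> None:
        self.log_lines.append(msg)

    # -- input loading ------------------------------------------------------

    def load_inputs(self):
        cfg = self.config
        sizes = pd.read_csv(cfg.genome, sep="\t")
        self.chrom_sizes = dict(zip(sizes["chrom"].astype(str), sizes["size"].astype(int)))
        self.genes, self.tes = mcalls.read_annotations(cfg.genes, cfg.tes)
        self.replicates: dict[str, list[pd.DataFrame]] = {}
        self.merged: dict[str, pd.DataFrame] = {}
        for tissue in cfg.tissues:
            reps = [mcalls.read_calls(p, cfg.dialect) for p in cfg.calls[tissue]]
            self.replicates[tissue] = reps
            self.merged[tissue] = mcalls.merge_replicates(*reps)
            self.log(
                f"input\ttissue={tissue}\treplicates={len(reps)}\t"
                f"sites_merged={len(self.merged[tissue])}"
            )
        self.counts = None
        self.samples = None
        if cfg.counts and cfg.samples:
            self.counts = pd.read_csv(cfg.counts, sep="\t", index_col="gene_id")
            self.samples = pd.read_csv(cfg.samples, sep="\t")
        self.tf_ids = set()
        if cfg.tf_genes:
            with open(cfg.tf_genes) as fh:
                self.tf_ids = {line.strip() for line in fh if line.strip()}
        self.gene_terms = {}
        if cfg.term_map:
            self.gene_terms, _ = mintegrate.read_term_map(cfg.term_map)
        self.gene_lengths = pd.Series(
            {g.gene_id: g.length for g in self.genes}, name="length"
        )

    # -- stages -------------------------------------------------------------

    def stage_profiles(self, params):
        out = {}
        window = params["window"]
        for tissue in self.config.tissues:
            prof = mprof.window_methylation(self.merged[tissue], self.chrom_sizes, window)
            prof = mprof.annotate_densities(prof, self.genes, self.tes)
            mprof.write_profile_tsv(prof, self.outdir / f"profile_{tissue}.tsv")
            corr = {}
            for which in ("gene", "te"):
                for ctx in CONTEXTS:
                    try:
                        r, p = mprof.density_correlation(prof, which, ctx)
                    except ValueError:
                        r, p = np.nan, np.nan
                    corr[f"{which}_{ctx}"] = {"r": r, "p": p}
            props = mprof.context_proportions(
                self.merged[tissue], "binomial", params["error_rate"]
            )
            rep_r = np.nan
            reps = self.replicates[tissue]
            if len(reps) >= 2:
                rep_r = mprof.replicate_correlation(
                    reps[0], reps[1], self.chrom_sizes, params["replicate_window"]
                )
            global_levels = {
                ctx: mcalls.weighted_level(self.merged[tissue], context=ctx)
                for ctx in CONTEXTS
            }
            out[tissue] = {
                "global_levels": global_levels,
                "context_proportions": props,
                "replicate_correlation_CG": rep_r,
                "density_correlations": corr,
            }
            self.log(
                f"profiles\ttissue={tissue}\twindows={len(prof.table)}\t"
                f"replicate_r={rep_r:.4f}" if rep_r == rep_r else
                f"profiles\ttissue={tissue}\twindows={len(prof.table)}"
            )
        tedist = mprof.te_distance_profile(self.tes, self.genes,
                                           self.merged[self.config.tissues[0]])
        tedist.to_csv(self.outdir / "te_distance_chh.tsv", sep="\t", index=False,
                      float_format="%.6g")
        self.summary["profiles"] = out

    def stage_metaplot(self, params):
        ref = self.config.tissues[0]
        kw = dict(params)
        out = {}
        for tissue in self.config.tissues:
            profs = {}
            for ctx in CONTEXTS:
                profs[ctx] = mmeta.metaplot(self.merged[tissue], self.genes, ctx, **kw)
            mmeta.write_metaprofile_tsv(profs, self.outdir / f"metaplot_genes_{tissue}.tsv")
        te_profiles = {}
        for ctx in CONTEXTS:
            for cls in ("I", "II"):
                members = [t for t in self.tes if t.te_class == cls]
                te_profiles[f"{ctx}_class{cls}"] = mmeta.metaplot(
                    self.merged[ref], members, ctx, group_label=f"class{cls}", **kw
                )
        mmeta.write_metaprofile_tsv(te_profiles, self.outdir / f"metaplot_tes_{ref}.tsv")
        excl = {}
        for ctx in CONTEXTS:
            all_p, free_p, frac = mmeta.metaplot_excluding_te_genes(
                self.merged[ref], self.genes, self.tes, ctx, **kw
            )
            mmeta.write_metaprofile_tsv(
                {"all_genes": all_p, "te_free_genes": free_p},
                self.outdir / f"metaplot_te_exclusion_{ref}_{ctx}.tsv",
            )
            excl[ctx] = {"excluded_fraction": frac}
        out["te_gene_exclusion"] = excl

        if self.counts is not None:
            fpkm = mexpr.compute_fpkm(
                self.counts, self.gene_lengths,
                self._library_sizes(),
            )
            tissue_fpkm = mexpr.fpkm_per_tissue(
                fpkm, self.samples.set_index("sample")["tissue"]
            )[ref]
            for scheme in ("binary", "clusters"):
                groups = mmeta.group_by_expression(tissue_fpkm, scheme)
                for ctx in CONTEXTS:
                    profs = mmeta.group_metaplots(
                        self.merged[ref], self.genes, groups, ctx, **kw
                    )
                    mmeta.write_metaprofile_tsv(
                        profs, self.outdir / f"metaplot_{scheme}_{ref}_{ctx}.tsv"
                    )
            groups = mmeta.group_by_expression(tissue_fpkm, "binary")
            tests = {}
            for region in ("upstream", "body"):
                for ctx in CONTEXTS:
                    res = mmeta.expressed_vs_unexpressed_test(
                        self.merged[ref], self.genes, groups, region, ctx,
                        params["flank_bp"],
                    )
                    tests[f"{region}_{ctx}"] = {
                        "difference": res["difference"], "p": res["p"],
                    }
            out["expressed_vs_unexpressed"] = tests
            quart = {}
            for region in ("upstream", "body"):
                for ctx in CONTEXTS:
                    try:
                        res = mmeta.quartile_expression_test(
                            self.merged[ref], self.genes, tissue_fpkm,
                            region, ctx, params["flank_bp"],
                        )
                    except ValueError:
                        continue
                    quart[f"{region}_{ctx}"] = {
                        "median_fpkm": res["median_fpkm"],
                        "p_Q1_Q4": res["pvalues"][("Q1", "Q4")],
                    }
            out["methylation_quartiles"] = quart
        self.summary["metaplot"] = out
        self.log(f"metaplot\tgenes={len(self.genes)}\ttes={len(self.tes)}")

    def _library_sizes(self) -> pd.Series | None:
        if self.samples is not None and "library_size" in self.samples.columns:
            return self.samples.set_index("sample")["library_size"]
        return None

    def stage_dmr(self, params):
        config = mdmr.DMRConfig(
            bin_size=params["bin_size"],
            min_site_coverage=params["min_site_coverage"],
            min_sites_per_bin=params["min_sites_per_bin"],
            diff_thresholds=dict(params["diff_thresholds"]),
            q_threshold=params["q_threshold"],
        )
        out = {}
        self.dmrs_by_comparison: dict[str, pd.DataFrame] = {}
        for a, b in _comparisons(self.config.tissues):
            name = f"{a}_vs_{b}"
            pieces = []
            counts = {}
            for ctx in CONTEXTS:
                res = mdmr.call_dmrs(self.merged[a], self.merged[b], config, ctx)
                pieces.append(res.dmrs)
                counts[ctx] = {
                    "tested_bins": res.n_tested,
                    "dmrs": len(res.dmrs),
                    "hyper": int((res.dmrs["direction"] == "hyper").sum()),
                    "hypo": int((res.dmrs["direction"] == "hypo").sum()),
                }
                self.log(
                    f"dmr\tcomparison={name}\tcontext={ctx}\t"
                    f"tested={res.n_tested}\tcalled={len(res.dmrs)}"
                )
            dmrs = pd.concat(pieces, ignore_index=True)
            dmrs, fractions = mdmr.classify_features(
                dmrs, self.genes, self.tes, self.chrom_sizes, params["flank_bp"]
            )
            mdmr.write_dmr_tsv(dmrs, self.outdir / f"dmrs_{name}.tsv")
            mdmr.write_dmr_bed(dmrs, self.outdir / f"dmrs_{name}.bed")
            self.dmrs_by_comparison[name] = dmrs
            feature_counts = dmrs["feature_class"].value_counts().to_dict()
            out[name] = {
                "per_context": counts,
                "feature_classes": feature_counts,
            }
        out["genome_partition"] = fractions
        first = _comparisons(self.config.tissues)[0]
        profile = mdmr.dmr_gene_profile(
            self.dmrs_by_comparison[f"{first[0]}_vs_{first[1]}"], self.genes,
            params["flank_bp"],
        )
        profile.to_csv(self.outdir / "dmr_gene_profile.tsv", sep="\t", index=False,
                       float_format="%.6g")
        self.summary["dmr"] = out

    def stage_dmv(self, params):
        per_tissue_bins, shared_bins = mdmv.scan_dmv_bins(
            self.merged, self.chrom_sizes, params["bin_size"],
            params["max_level"], params["min_reads"],
        )
        per_tissue = {
            t: mdmv.merge_dmvs(bins, params["bin_size"])
            for t, bins in per_tissue_bins.items()
        }
        shared = mdmv.merge_dmvs(shared_bins, params["bin_size"])
        genome_size = sum(self.chrom_sizes.values())
        summary = mdmv.dmv_summary(per_tissue, genome_size)
        summary["shared_count_from_bins"] = len(shared)
        for t, dmvs in per_tissue.items():
            mdmv.write_dmv_bed(dmvs, self.outdir / f"dmvs_{t}.bed")
        mdmv.write_dmv_bed(shared, self.outdir / "dmvs_shared.bed")
        gene_sets = mdmv.assign_dmv_genes(
            shared, self.genes, params["gene_flank"], params["mode"]
        )
        mdmv.write_dmv_genes_tsv(gene_sets, params["mode"],
                                 self.outdir / "dmv_genes.tsv")
        self.dmv_gene_ids = set().union(*gene_sets.values()) if gene_sets else set()
        self.shared_dmvs = shared
        enrich = None
        if self.tf_ids:
            all_ids = {g.gene_id for g in self.genes}
            enrich = mdmv.tf_enrichment(self.dmv_gene_ids, all_ids, self.tf_ids)
            enrich = {
                "table": enrich["table"].tolist(),
                "statistic": enrich["statistic"],
                "p": enrich["p"],
                "proportion_dmv": enrich["proportion_dmv"],
                "proportion_other": enrich["proportion_other"],
                "tf_percent_of_dmv_genes": mdmv.tf_proportion_percent(
                    int(enrich["table"][0][0]),
                    max(int(enrich["table"][0][0]) + int(enrich["table"][0][1]), 1),
                ),
            }
        self.summary["dmv"] = {
            "counts_per_tissue": summary["counts_per_tissue"],
            "shared_count": summary["shared_count"],
            "nonredundant_count": summary["nonredundant_count"],
            "nonredundant_bp": summary["nonredundant_bp"],
            "genome_fraction": summary["genome_fraction"],
            "shared_percent_candidates": summary["shared_percent_candidates"],
            "n_dmv_genes": len(self.dmv_gene_ids),
            "tf_enrichment": enrich,
        }
        self.log(
            "dmv\t" + "\t".join(
                f"{t}={len(v)}" for t, v in per_tissue.items()
            ) + f"\tshared={len(shared)}"
        )

    def stage_expr(self, params):
        if self.counts is None:
            self.summary["expr"] = {"skipped": "no counts matrix configured"}
            return
        fpkm = mexpr.compute_fpkm(self.counts, self.gene_lengths, self._library_sizes())
        fpkm.reset_index().to_csv(self.outdir / "fpkm.tsv", sep="\t", index=False,
                                  float_format="%.6g")
        tissue_map = self.samples.set_index("sample")["tissue"]
        tissue_fpkm = mexpr.fpkm_per_tissue(fpkm, tissue_map)
        classes = {}
        for tissue in self.config.tissues:
            if tissue in tissue_fpkm.columns:
                cls = mexpr.classify_expression(tissue_fpkm[tissue],
                                                params["fpkm_threshold"])
                classes[tissue] = {
                    "expressed": int((cls == "expressed").sum()),
                    "unexpressed": int((cls == "unexpressed").sum()),
                }
        self.degs_by_comparison: dict[str, pd.DataFrame] = {}
        deg_counts = {}
        for a, b in _comparisons(self.config.tissues):
            name = f"{a}_vs_{b}"
            cols_a = self.samples.loc[self.samples["tissue"] == a, "sample"]
            cols_b = self.samples.loc[self.samples["tissue"] == b, "sample"]
            degs = mexpr.call_degs(
                self.counts[list(cols_a)], self.counts[list(cols_b)],
                params["min_fold"], params["q_threshold"],
            )
            mexpr.write_deg_tsv(degs, self.outdir / f"degs_{name}.tsv")
            self.degs_by_comparison[name] = degs
            deg_counts[name] = {
                "degs": int(degs["is_deg"].sum()),
                "up": int((degs["is_deg"] & (degs["direction"] == "up")).sum()),
                "down": int((degs["is_deg"] & (degs["direction"] == "down")).sum()),
            }
            self.log(f"expr\tcomparison={name}\tdegs={deg_counts[name]['degs']}")
        self.summary["expr"] = {
            "expression_classes": classes,
            "deg_counts": deg_counts,
            "total_degs_union": int(
                len(
                    set().union(
                        *(
                            set(d.index[d["is_deg"]])
                            for d in self.degs_by_comparison.values()
                        )
                    )
                )
            ) if self.degs_by_comparison else 0,
        }

    def stage_integrate(self, params):
        out = {}
        have_dmr = hasattr(self, "dmrs_by_comparison")
        have_deg = hasattr(self, "degs_by_comparison")
        all_ids = {g.gene_id for g in self.genes}
        if have_dmr and have_deg:
            results = []
            for name, dmrs in self.dmrs_by_comparison.items():
                if name not in self.degs_by_comparison:
                    continue
                dmr_gene_ids = mintegrate.dmr_gene_overlap(
                    dmrs, self.genes, params["flank_bp"]
                )
                degs = self.degs_by_comparison[name]
                deg_ids = set(degs.index[degs["is_deg"]])
                if not deg_ids:
                    continue
                res = mintegrate.deg_dmr_association(deg_ids, dmr_gene_ids, all_ids, name)
                results.append(res)
                out[name] = {
                    "proportion_deg_with_dmr": res.proportion_deg_with_dmr,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p,
                    "n_dmr_genes": len(dmr_gene_ids),
                }
            mintegrate.write_association_tsv(results, self.outdir / "deg_dmr_association.tsv")
        if self.gene_terms and hasattr(self, "dmv_gene_ids") and self.dmv_gene_ids:
            enr = mintegrate.term_enrichment(
                self.dmv_gene_ids, all_ids, self.gene_terms, params["q_threshold"]
            )
            enr.to_csv(self.outdir / "dmv_gene_term_enrichment.tsv", sep="\t",
                       index=False, float_format="%.6g")
            out["dmv_gene_terms_significant"] = int(enr["significant"].sum()) if len(enr) else 0
        self.summary["integrate"] = out
        self.log(f"integrate\tcomparisons={len(out)}")

    # -- driver -------------------------------------------------------------

    def run(self) -> dict:
        self.config.validate()
        self.load_inputs()
        params = _merged_params(self.config.params)
        failed = None
        for stage in STAGES:
            if not self.config.stages.get(stage, True):
                self.stage_status[stage] = "skipped"
                continue
            try:
                getattr(self, f"stage_{stage}")(params[stage])
                self.stage_status[stage] = "ok"
            except Exception as exc:  # partial outputs retained
                self.stage_status[stage] = f"failed: {exc}"
                failed = stage
                break
        summary_path = self.outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(_jsonable(self.summary), fh, indent=1, sort_keys=True)
        log_path = self.outdir / "log.txt"
        with open(log_path, "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")
        manifest = {
            "stages": self.stage_status,
            "failed": failed,
            "files": {},
        }
        for path in sorted(self.outdir.iterdir()):
            if path.name == "manifest.json" or not path.is_file():
                continue
            manifest["files"][path.name] = _sha256(path)
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        if failed is not None:
            raise PipelineError(f"stage {failed} failed: {self.stage_status[failed]}")
        return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if f != f else round(f, 10)
    return obj


def run_pipeline(config, outdir) -> dict:
    """Run the pipeline from a :class:`RunConfig` or a YAML config path."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    return PipelineRun(config, outdir).run()


def write_default_config(study_dir, path, tissues, n_replicates: int) -> None:
    """Emit a run config YAML pointing at a written simulation study."""
    study_dir = Path(study_dir).resolve()
    cfg = {
        "paths": {
            "genome": str(study_dir / "genome.tsv"),
            "genes": str(study_dir / "genes.gff3"),
            "tes": str(study_dir / "tes.bed"),
            "counts": str(study_dir / "counts.tsv"),
            "samples": str(study_dir / "samples.tsv"),
            "tf_genes": str(study_dir / "tf_genes.txt"),
            "term_map": str(study_dir / "term_map.tsv"),
            "calls": {
                t: [str(study_dir / f"calls_{t}_r{r}.tsv")
                    for r in range(1, n_replicates + 1)]
                for t in tissues
            },
        },
        "tissues": list(tissues),
        "dialect": "methratio",
        "stages": {s: True for s in STAGES},
        "params": {},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
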