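"""End-to-end orchestration of the analysis stages.

A run is a pure function of (fixture inputs, configuration, seed): global
methylation summaries, percent-change reporting with two-proportion
z-tests, per-comparison DMR calling and annotation, TE-length enrichment,
expression filters and MDS, and the promoter correlation analysis.  Every
stage writes a delimited table; a JSON manifest records the effective
parameters, versions and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.proportion import proportions_ztest

from . import correlation as corr_mod
from . import dmr as dmr_mod
from . import expression as expr_mod
from . import methylome as meth_mod
from . import te as te_mod
from .errors import ConfigError
from .synthetic import SimulationConfig, read_fixture, simulate_all, write_fixture

log = logging.getLogger("rootmeth")

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Every stage threshold, defaulting to the study's printed values."""

    input_dir: str = "fixture"
    out_dir: str = "results"
    seed: int = 0
    context: str = "CHH"
    window_width: int = 50
    min_informative: int = 20
    informative_rule: str = "per_sample"
    dmr_thresholds: dict = field(
        default_factory=lambda: dict(dmr_mod.CONTEXT_THRESHOLDS)
    )
    alpha: float = 0.05
    rpkm_transcribed: float = 1.0
    rpkm_max: float = 2.0
    min_cv: float = 1.0
    min_fold: float = 4.0
    max_q: float = 0.01
    promoter_span: int = 2000
    promoter_bin: int = 200
    fdr_q: float = 0.01
    short_te_cutoff: int = 500
    control_per_chrom: int = 2000
    metaplot_flank: int = 2000
    metaplot_body_bins: int = 20
    metaplot_flank_bins: int = 10
    mds_dimensions: int = 3
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim) - sim_known
        if bad:
            raise ConfigError(f"unknown simulation keys: {sorted(bad)}")
        if "baseline_methylation" in sim:
            sim["baseline_methylation"] = tuple(sim["baseline_methylation"])
        cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["baseline_methylation"] = list(
            d["simulation"]["baseline_methylation"]
        )
        return d


def report_percent_changes(levels: pd.DataFrame) -> pd.DataFrame:
    """Pairwise consecutive-stage percent changes with a two-proportion
    z-test on pooled methylated/total counts.

    ``levels`` needs columns sample, mc_total, cov_total (one row per
    sample, in stage order).
    """
    rows = []
    for i in range(1, len(levels)):
        before, after = levels.iloc[i - 1], levels.iloc[i]
        lv_before = before["mc_total"] / before["cov_total"]
        lv_after = after["mc_total"] / after["cov_total"]
        magnitude, direction = meth_mod.describe_percent_change(lv_before, lv_after)
        if before["mc_total"] + after["mc_total"] in (
            0,
            before["cov_total"] + after["cov_total"],
        ):
            p = 1.0
        else:
            _, p = proportions_ztest(
                [after["mc_total"], before["mc_total"]],
                [after["cov_total"], before["cov_total"]],
            )
        rows.append(
            (
                f"{after['sample']}_vs_{before['sample']}",
                lv_before,
                lv_after,
                magnitude,
                direction,
                float(p),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["comparison", "level_before", "level_after", "percent_change", "direction", "z_p_value"],
    )


def run_simulate(config: PipelineConfig) -> dict[str, str]:
    """Generate the synthetic fixture into ``config.input_dir``."""
    sim = dataclasses.replace(config.simulation)
    log.info("simulating fixture (seed=%d) into %s", sim.seed, config.input_dir)
    annotation, tracks, matrix, truth = simulate_all(sim)
    return write_fixture(config.input_dir, annotation, tracks, matrix, truth)


class Pipeline:
    """Stage-by-stage executor over a loaded fixture."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.counts: dict[str, int] = {}
        os.makedirs(config.out_dir, exist_ok=True)

    # -- I/O helpers -------------------------------------------------------
    def _write(self, name: str, frame: pd.DataFrame) -> None:
        path = os.path.join(self.config.out_dir, name)
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        self.counts[name] = len(frame)
        log.info("wrote %s (%d rows)", path, len(frame))

    def load(self) -> None:
        self.annotation, self.tracks, self.matrix, self.truth = read_fixture(
            self.config.input_dir
        )
        if not self.tracks:
            raise ConfigError(
                f"no methylome tracks found in {self.config.input_dir} "
                "(stage: global methylation)"
            )
        self.samples: list[str] = []
        self.tracks_by_sample: dict[str, list] = {}
        for t in self.tracks:
            if t.sample not in self.tracks_by_sample:
                self.samples.append(t.sample)
                self.tracks_by_sample[t.sample] = []
            self.tracks_by_sample[t.sample].append(t)

    # -- stages ------------------------------------------------------------
    def global_methylation(self) -> pd.DataFrame:
        cfg = self.config
        rows = []
        for sample in self.samples:
            tracks = self.tracks_by_sample[sample]
            for context in meth_mod.CONTEXTS:
                s = meth_mod.weighted_methylation(tracks, context)
                bins = meth_mod.methylation_by_100kb(
                    tracks, context, self.annotation.chrom_lengths
                )
                rows.append(
                    (
                        sample,
                        context,
                        s.mc_total,
                        s.cov_total,
                        s.level,
                        float(bins["level"].median()) if len(bins) else np.nan,
                    )
                )
        out = pd.DataFrame(
            rows,
            columns=["sample", "context", "mc_total", "cov_total", "level", "median_100kb"],
        )
        self._write("global_methylation.tsv", out)

        levels = out[out["context"] == cfg.context][["sample", "mc_total", "cov_total"]]
        changes = report_percent_changes(levels.reset_index(drop=True))
        self._write("percent_changes.tsv", changes)
        self.global_levels = out
        return out

    def call_dmrs(self) -> dict[str, pd.DataFrame]:
        cfg = self.config
        self.dmr_tables: dict[str, pd.DataFrame] = {}
        summaries = []
        for i in range(1, len(self.samples)):
            a, b = self.samples[i], self.samples[i - 1]  # later vs earlier
            for context in meth_mod.CONTEXTS:
                counts = dmr_mod.window_counts(
                    self.tracks_by_sample[a],
                    self.tracks_by_sample[b],
                    self.annotation.chrom_lengths,
                    context,
                    cfg.window_width,
                )
                dmrs = dmr_mod.call_dmrs(
                    counts,
                    cfg.min_informative,
                    cfg.dmr_thresholds,
                    cfg.alpha,
                    cfg.informative_rule,
                )
                dmrs = dmr_mod.annotate_dmrs(dmrs, self.annotation, cfg.promoter_span)
                key = f"{a}_vs_{b}_{context}"
                self.dmr_tables[key] = dmrs
                out = dmrs.copy()
                out["start"] = out["start"] + 1  # 1-based inclusive on disk
                self._write(f"dmrs_{key}.tsv", out)
                s = dmr_mod.summarize_dmrs(dmrs)
                s.insert(0, "comparison", key)
                summaries.append(s)
        self._write(
            "dmr_summary.tsv",
            pd.concat(summaries, ignore_index=True)
            if summaries
            else pd.DataFrame(columns=["comparison", "direction", "feature", "count"]),
        )
        return self.dmr_tables

    def te_enrichment(self) -> None:
        cfg = self.config
        chh_keys = [k for k in self.dmr_tables if k.endswith("_CHH")]
        dmr_windows = pd.concat(
            [self.dmr_tables[k][["chrom", "start", "end"]] for k in chh_keys],
            ignore_index=True,
        ).drop_duplicates()
        controls = te_mod.sample_control_windows(
            self.annotation.chrom_lengths,
            cfg.control_per_chrom,
            cfg.window_width,
            np.random.default_rng([cfg.seed, 10]),
        )
        dmr_lengths = te_mod.associated_te_lengths(dmr_windows, self.annotation.tes)
        ctrl_lengths = te_mod.associated_te_lengths(controls, self.annotation.tes)
        if len(dmr_lengths) and len(ctrl_lengths):
            cmp = te_mod.compare_length_distributions(
                dmr_lengths, ctrl_lengths, cfg.short_te_cutoff
            )
            self._write(
                "te_length_comparison.tsv",
                pd.DataFrame([dataclasses.asdict(cmp)]),
            )
        else:
            log.warning("TE length comparison skipped: an associated set is empty")
        profile = te_mod.short_te_genic_profile(
            self.annotation.tes,
            self.annotation.genes,
            cfg.short_te_cutoff,
            cfg.metaplot_flank,
            cfg.metaplot_body_bins,
            cfg.metaplot_flank_bins,
        )
        self._write("short_te_profile.tsv", profile)

    def metaplots(self) -> None:
        cfg = self.config
        frames = []
        for features, label in ((self.annotation.genes, "gene"), (self.annotation.tes, "TE")):
            if len(features) == 0:
                continue
            for sample in self.samples:
                prof = meth_mod.metaplot(
                    self.tracks_by_sample[sample],
                    features,
                    cfg.context,
                    cfg.metaplot_flank,
                    cfg.metaplot_body_bins,
                    cfg.metaplot_flank_bins,
                )
                prof.insert(0, "feature", label)
                prof.insert(1, "sample", sample)
                frames.append(prof)
        if frames:
            self._write("metaplots.tsv", pd.concat(frames, ignore_index=True))

    def expression(self) -> None:
        cfg = self.config
        transcribed = expr_mod.count_transcribed(self.matrix, cfg.rpkm_transcribed)
        self._write(
            "transcribed_counts.tsv",
            transcribed.rename_axis("sample").reset_index(),
        )
        self.retained = expr_mod.variation_filter(self.matrix, cfg.rpkm_max, cfg.min_cv)
        self._write(
            "variation_filtered_genes.tsv", pd.DataFrame({"gene": self.retained})
        )
        n_samples = self.matrix.shape[1]
        if n_samples >= cfg.mds_dimensions + 1:
            dist, coords, stress = expr_mod.mds_embedding(self.matrix, cfg.mds_dimensions)
            coords = coords.rename_axis("sample").reset_index()
            coords["stress"] = stress
            self._write("mds_coordinates.tsv", coords)
        else:
            log.warning("MDS skipped: %d samples < %d", n_samples, cfg.mds_dimensions + 1)

    def correlate(self) -> pd.DataFrame:
        cfg = self.config
        means = expr_mod.stage_means(self.matrix)
        means = means[[s for s in self.samples if s in means.columns]]
        table = corr_mod.correlate_genes(
            self.tracks_by_sample,
            self.annotation,
            means.loc[means.index.intersection(self.retained)],
            cfg.context,
            cfg.promoter_span,
            cfg.promoter_bin,
            cfg.fdr_q,
        )
        self._write("correlation.tsv", table)
        tested = table[np.isfinite(table["p_value"].to_numpy(dtype=float))]
        n_sig = int((tested["sign_class"] != "none").sum())
        self.correlation_summary = {
            "n_tested": int(len(tested)),
            "n_significant": n_sig,
            "fraction_percent": (
                corr_mod.classified_fraction(n_sig, len(tested)) if len(tested) else None
            ),
        }
        return table

    def manifest(self) -> dict:
        import rootmeth

        info = {
            "package_version": rootmeth.__version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": self.config.seed,
            "parameters": self.config.to_dict(),
            "row_counts": self.counts,
            "correlation_summary": getattr(self, "correlation_summary", None),
        }
        path = os.path.join(self.config.out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(info, fh, indent=2, sort_keys=True)
        return info


def run_full_analysis(config: PipelineConfig) -> Pipeline:
    """Execute every stage in order; any stage failure names the stage."""
    pipe = Pipeline(config)
    stages = [
        ("load inputs", pipe.load),
        ("global methylation", pipe.global_methylation),
        ("DMR calling", pipe.call_dmrs),
        ("TE enrichment", pipe.te_enrichment),
        ("metaplots", pipe.metaplots),
        ("expression", pipe.expression),
        ("correlation", pipe.correlate),
    ]
    for name, fn in stages:
        log.info("stage: %s", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    pipe.manifest()
    return pipe
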