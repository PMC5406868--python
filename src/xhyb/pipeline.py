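"""End-to-end orchestration: simulate/load -> mask -> RMA -> calls -> DE ->
classification -> networks -> report bundle.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
one seed; all stochastic stages draw their seeds from that one seed in a
fixed order, so a run is replayable bit-for-bit.  Every stage logs counts
in/out and any stage failure aborts with the stage name.  The report bundle
is a directory of TSV tables (threshold sweep, mask comparison, expressed
calls, per-contrast DEG counts, DEG tables with response classes, the
cross-genotype common-DEG table, PCA variance fractions, TF degree tables)
plus exported networks and a JSON manifest with the config and input
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chipmodel, differential, expression_calls, masking, network, summarization
from .chipmodel import ValidationError
from .summarization import SummarizationConfig
from . import synthetic_data

log = logging.getLogger("xhyb")

CONTRAST_PAIRS = {
    "stress": ("water_limited", "water_sufficient"),
    "recovery_vs_ws": ("recovery", "water_sufficient"),
    "stress_vs_recovery": ("water_limited", "recovery"),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class SimulateConfig:
    """Parameters of the emulated study when inputs are simulated."""

    n_sets: int = 2000
    pairs_per_set: int = 11
    genotypes: tuple[str, ...] = ("DipC", "TN")
    bind_prob: float = 0.9
    n_de_per_genotype: int = 100
    n_common_de: int = 9
    frac_responsive: float = 0.75
    log2fc_range: tuple[float, float] = (1.1, 2.0)
    n_modules: int = 0
    module_size: int = 10
    noise_sd: float = 0.25


@dataclass
class RunConfig:
    outdir: str = "xhyb_run"
    seed: int = 0
    simulate: bool = True
    sim: SimulateConfig = field(default_factory=SimulateConfig)
    # user-supplied inputs (used when simulate=False)
    layout_path: str | None = None
    gdna_path: str | None = None
    rna_path: str | None = None
    sheet_path: str | None = None
    annotations_path: str | None = None
    exclude_samples: tuple[str, ...] = ()
    # masking
    mask_threshold: float = 256.0
    min_pairs_per_set: int = 1
    sweep_points: int = 12
    sweep_thresholds: tuple[float, ...] | None = None
    # summarization
    summarization: SummarizationConfig = field(default_factory=SummarizationConfig)
    # expressed calls
    expressed_window: int = 51
    expressed_cutoff: float | None = None
    # differential expression
    q_max: float = 0.05
    fc_min: float = 2.0
    pooled: bool = False
    classify_rule: str = "nonsig_recovery"
    # network
    net_threshold: float = 0.9
    net_mode: str = "absolute"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimulateConfig(**_tuplify(d["sim"]))
        if "summarization" in d and isinstance(d["summarization"], dict):
            d["summarization"] = SummarizationConfig(**d["summarization"])
        return cls(**_tuplify(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=True)


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_listify(v) for v in obj]
    return obj


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: use as ``with``-less helper."""

    class _Guard:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            if exc is None:
                log.info("stage %s: done", name)
            return False

    return _Guard()


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns the report tables as a dict.

    All tables are also written under ``config.outdir`` with byte-stable
    content for a fixed config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in ("layout", "truth", "gdna", "rna")}
    report: dict = {}
    input_files: dict[str, str] = {}

    # ------------------------------------------------------------------ inputs
    with _stage("inputs"):
        truth = None
        if config.simulate:
            sim = config.sim
            layout = synthetic_data.simulate_layout(
                sim.n_sets, sim.pairs_per_set, seed=seeds["layout"]
            )
            truth = synthetic_data.simulate_truth(
                layout,
                n_de_per_genotype=sim.n_de_per_genotype,
                n_common_de=sim.n_common_de,
                frac_responsive=sim.frac_responsive,
                log2fc_range=sim.log2fc_range,
                n_modules=sim.n_modules,
                module_size=sim.module_size,
                genotypes=sim.genotypes,
                seed=seeds["truth"],
            )
            gdna = synthetic_data.simulate_gdna(
                layout, sim.bind_prob, seed=seeds["gdna"], truth=truth
            )
            sheet = synthetic_data.simulate_sample_sheet(sim.genotypes)
            rna = synthetic_data.simulate_rna(
                layout, truth, sheet, noise_sd=sim.noise_sd, seed=seeds["rna"]
            )
            truth.to_tsv(outdir / "truth.tsv")
        else:
            for label, p in (
                ("layout", config.layout_path),
                ("gdna", config.gdna_path),
                ("rna", config.rna_path),
                ("sheet", config.sheet_path),
            ):
                if p is None or not Path(p).exists():
                    raise ValidationError(f"missing input file for {label!r}: {p}")
                input_files[label] = _sha256(p)
            layout = chipmodel.read_layout(config.layout_path)
            sheet = chipmodel.read_sample_sheet(config.sheet_path)
            gdna = chipmodel.read_intensities(config.gdna_path, layout)
            rna = chipmodel.read_intensities(config.rna_path, layout)
        for sid in config.exclude_samples:
            sheet = sheet.exclude(sid)
        genotypes = sheet.genotypes
        annotations = None
        if config.annotations_path:
            annotations = pd.read_csv(config.annotations_path, sep="\t")
            input_files["annotations"] = _sha256(config.annotations_path)

    # ----------------------------------------------------------------- masking
    with _stage("masking"):
        taus = config.sweep_thresholds
        if taus is None:
            arr = gdna.values.to_numpy().ravel()
            taus = tuple(
                np.geomspace(
                    np.quantile(arr, 0.01), np.quantile(arr, 0.999), config.sweep_points
                )
            )
        sweep = masking.sweep_thresholds(
            gdna, layout, taus, min_pairs_per_set=config.min_pairs_per_set
        )
        sweep.to_csv(outdir / "threshold_sweep.tsv", sep="\t", index=False)
        report["threshold_sweep"] = sweep

        masks = {}
        for g in genotypes:
            col = f"gdna_{g}" if f"gdna_{g}" in gdna.sample_ids else g
            if col not in gdna.sample_ids:
                raise ValidationError(f"no gDNA column for genotype {g!r}")
            masks[g] = masking.select_probe_pairs(
                gdna.values[col],
                layout,
                config.mask_threshold,
                min_pairs_per_set=config.min_pairs_per_set,
                genotype=g,
            )
            masking.write_custom_definition(
                masks[g], layout, outdir / f"custom_definition_{g}.tsv"
            )
            log.info(
                "mask %s: %d pairs, %d sets at tau=%g",
                g, masks[g].n_pairs, masks[g].n_sets, config.mask_threshold,
            )
        if len(genotypes) >= 2:
            a, b = genotypes[0], genotypes[1]
            n_common, n_a, n_b = masking.compare_masks(masks[a], masks[b])
            cmp_df = pd.DataFrame(
                [
                    {
                        "threshold": config.mask_threshold,
                        "n_common_sets": n_common,
                        f"n_specific_{a}": n_a,
                        f"n_specific_{b}": n_b,
                    }
                ]
            )
            cmp_df.to_csv(outdir / "mask_comparison.tsv", sep="\t", index=False)
            report["mask_comparison"] = cmp_df

    # ------------------------------------------------------------ summarization
    with _stage("summarization"):
        exprs = {}
        active = sheet.active()
        for g in genotypes:
            cols = list(active.loc[active["genotype"] == g, "sample_id"])
            sub = chipmodel.ProbeIntensityMatrix(rna.values[cols])
            exprs[g] = summarization.rma_summarize(
                sub, masks[g], layout, config.summarization
            )
            chipmodel.write_expression(exprs[g], outdir / f"expression_{g}.tsv")

    # ---------------------------------------------------------- expressed calls
    with _stage("expressed_calls"):
        calls = {}
        rows = []
        for g in genotypes:
            ws = sheet.samples_for(g, "water_sufficient")
            calls[g] = expression_calls.call_expressed(
                exprs[g],
                samples=ws,
                override_cutoff=config.expressed_cutoff,
                smoothing_window=config.expressed_window,
            )
            rows.append(
                {
                    "genotype": g,
                    "cutoff_relative_value": calls[g].cutoff_relative_value,
                    "cutoff_rank_fraction": calls[g].cutoff_rank_fraction,
                    "n_expressed": calls[g].n_expressed,
                }
            )
        if len(genotypes) >= 2:
            a, b = genotypes[0], genotypes[1]
            n_shared = len(calls[a].expressed_sets & calls[b].expressed_sets)
            for r in rows:
                r["n_expressed_common"] = n_shared
        expressed_df = pd.DataFrame(rows)
        expressed_df.to_csv(outdir / "expressed_calls.tsv", sep="\t", index=False)
        report["expressed_calls"] = expressed_df

    # ------------------------------------------------------------- differential
    with _stage("differential_expression"):
        contrasts: dict[tuple[str, str], pd.DataFrame] = {}
        degs: dict[tuple[str, str], pd.DataFrame] = {}
        count_rows = []
        for g in genotypes:
            for cname, pair in CONTRAST_PAIRS.items():
                c = differential.contrast(
                    exprs[g], sheet, g, pair, pooled=config.pooled
                )
                contrasts[(g, cname)] = c
                keep = (c["q"] <= config.q_max) & (c["fold_change"] > config.fc_min)
                d = c.loc[keep].copy()
                d.insert(0, "contrast", c.attrs["contrast"])
                d["response_class"] = "unclassified"
                degs[(g, cname)] = d.reset_index(drop=True)
                count_rows.append(
                    {
                        "genotype": g,
                        "contrast": cname,
                        "n_deg": len(d),
                        "n_up": int((d["direction"] == "up").sum()),
                        "n_down": int((d["direction"] == "down").sum()),
                    }
                )
                log.info("%s %s: %d DEGs", g, cname, len(d))
        deg_counts = pd.DataFrame(count_rows)
        deg_counts.to_csv(outdir / "deg_counts.tsv", sep="\t", index=False)
        report["deg_counts"] = deg_counts

    # ------------------------------------------------------------ classification
    with _stage("response_classification"):
        stress_degs = {}
        class_rows = []
        for g in genotypes:
            follow = (
                contrasts[(g, "recovery_vs_ws")]
                if config.classify_rule == "nonsig_recovery"
                else contrasts[(g, "stress_vs_recovery")]
            )
            classified = differential.classify_response(
                degs[(g, "stress")],
                follow,
                q_max=config.q_max,
                fc_min=config.fc_min,
                rule=config.classify_rule,
            )
            stress_degs[g] = classified
            classified.drop(columns=["degenerate"]).to_csv(
                outdir / f"degs_{g}.tsv", sep="\t", index=False
            )
            n = len(classified)
            n_resp = int((classified["response_class"] == "responsive").sum())
            n_pert = int((classified["response_class"] == "perturbed").sum())
            class_rows.append(
                {
                    "genotype": g,
                    "n_stress_degs": n,
                    "n_responsive": n_resp,
                    "n_perturbed": n_pert,
                    "frac_responsive": n_resp / n if n else float("nan"),
                }
            )
        classes_df = pd.DataFrame(class_rows)
        classes_df.to_csv(outdir / "response_classes.tsv", sep="\t", index=False)
        report["response_classes"] = classes_df
        report["stress_degs"] = stress_degs

        if len(genotypes) >= 2:
            a, b = genotypes[0], genotypes[1]
            ov = differential.overlap_degs(stress_degs[a], stress_degs[b])
            common_df = pd.DataFrame(
                sorted(
                    [
                        {"probe_set_id": p, "direction": "up"}
                        for p in ov.common_up
                    ]
                    + [
                        {"probe_set_id": p, "direction": "down"}
                        for p in ov.common_down
                    ],
                    key=lambda r: r["probe_set_id"],
                ),
                columns=["probe_set_id", "direction"],
            )
            common_df.to_csv(outdir / "common_degs.tsv", sep="\t", index=False)
            report["common_degs"] = common_df
            report["deg_overlap"] = ov

    # --------------------------------------------------------------------- pca
    with _stage("pca"):
        shared = exprs[genotypes[0]].probe_set_ids
        for g in genotypes[1:]:
            shared = shared.intersection(exprs[g].probe_set_ids)
        joint = pd.concat(
            [exprs[g].values.loc[shared] for g in genotypes], axis=1
        )
        fractions, scores = differential.pca_variance(
            chipmodel.ExpressionMatrix(joint)
        )
        pca_df = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(fractions))],
                "variance_fraction": fractions,
            }
        )
        pca_df.to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="sample_id")
        report["pca_variance"] = pca_df
        report["pca_scores"] = scores

    # ----------------------------------------------------------------- network
    with _stage("network"):
        nets = {}
        degree_tables = {}
        for g in genotypes:
            whole_nodes = sorted(
                set().union(
                    *(set(degs[(g, c)]["probe_set_id"]) for c in CONTRAST_PAIRS)
                )
            )
            drought_nodes = set(degs[(g, "stress")]["probe_set_id"])
            if len(whole_nodes) < 2:
                nets[g] = network.build_network(
                    pd.DataFrame(
                        np.eye(len(whole_nodes)),
                        index=whole_nodes,
                        columns=whole_nodes,
                    ),
                    threshold=config.net_threshold,
                    mode=config.net_mode,
                    genotype_origin=g,
                )
            else:
                sub = chipmodel.ExpressionMatrix(
                    exprs[g].values.loc[whole_nodes]
                )
                corr = network.spearman_matrix(sub)
                dir_ann = (
                    stress_degs[g][["probe_set_id", "direction"]]
                    .drop_duplicates("probe_set_id")
                    .set_index("probe_set_id")
                )
                ann = dir_ann
                if annotations is not None:
                    ann = annotations.copy()
                    if "probe_set_id" in ann.columns:
                        ann = ann.set_index("probe_set_id")
                    ann = ann.join(dir_ann, how="outer")
                nets[g] = network.build_network(
                    corr,
                    threshold=config.net_threshold,
                    mode=config.net_mode,
                    annotations=ann.reset_index(),
                    genotype_origin=g,
                )
            network.export_network(nets[g], "graphml", outdir / f"network_{g}.graphml")
            network.export_network(nets[g], "sif", outdir / f"network_{g}.sif")
            degree_tables[g] = network.degree_table(
                nets[g], drought_nodes & set(nets[g].nodes),
                tf_only=annotations is not None,
            )
            degree_tables[g].to_csv(
                outdir / f"degree_{g}.tsv", sep="\t", index=False
            )
        report["networks"] = nets
        report["degree_tables"] = degree_tables
        if len(genotypes) >= 2:
            a, b = genotypes[0], genotypes[1]
            merged = network.merge_networks(nets[a], nets[b])
            network.export_network(merged, "graphml", outdir / "network_merged.graphml")
            report["merged_network"] = merged
            merged_deg = network.degree_table(
                merged, tf_only=annotations is not None
            )
            merged_deg.to_csv(outdir / "degree_merged.tsv", sep="\t", index=False)
            report["degree_merged"] = merged_deg

    # ---------------------------------------------------------------- manifest
    with _stage("manifest"):
        manifest = {
            "config": _listify(config.to_dict()),
            "stage_seeds": seeds,
            "inputs_sha256": input_files,
            "outputs": sorted(
                p.name for p in outdir.iterdir() if p.name != "manifest.json"
            ),
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        report["manifest"] = manifest
    if truth is not None:
        report["truth"] = truth
    report["expressions"] = exprs
    report["contrasts"] = contrasts
    report["masks"] = masks
    return report
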