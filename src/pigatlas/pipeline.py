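"""End-to-end orchestration: atlas -> intensities -> specificity / links /
TEs / variants -> machine-readable report.

The configuration is one hierarchical mapping (YAML or dict) holding every
threshold of the analysis with its standard default: fold 2.0, conserved
fraction 0.9, proximal window 1000 bp, cis window 500,000 bp, alpha 0.01,
TE overlap fractions 0.5/0.2, 100 permutations. Inputs are either file
paths or ``simulate: true``, in which case the synthetic generator
produces the study from ``simulation`` parameters and the run seed.

A rerun with identical config and inputs reproduces identical outputs;
``run_report.json`` is written with sorted keys so the bytes match too.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from . import io as pio
from .links import build_link_map, candidate_pairs, classify_sign_profiles, link_summary
from .quantify import (
    IntensityMatrix,
    SampleSheet,
    annotate_genomic_category,
    build_atlas,
    classify_proximal_distal,
    cluster_samples,
    filter_expressed,
)
from .simulate import SimulationConfig, simulate_study, write_study
from .specificity import (
    call_conserved,
    call_group_specific,
    call_specific,
    tissue_means,
)
from .te import call_accessible_tes, classify_sharing, permutation_enrichment, te_class_composition
from .variants import annotate_variants, prioritize_genes, variant_peak_enrichment

log = logging.getLogger("pigatlas.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "atlas_mode": "reproducible",  # union | reproducible | min_samples
    "min_samples": 2,
    "fold_threshold": 2.0,
    "conserved_fraction": 0.9,
    "proximal_bp": 1000,
    "link_window": 500_000,
    "alpha": 0.01,
    "expression_min_tpm": 1.0,
    "expression_min_fraction": 0.10,
    "te_fraction": 0.5,
    "peak_fraction": 0.2,
    "n_perm": 100,
    "cluster_top_n": None,
    "distance_bin_width": 20_000,
    "tissue_systems": None,  # tissue -> system mapping; None disables the stage
    "inputs": {"simulate": True},
    "simulation": {},  # overrides for SimulationConfig fields
}

_SCHEMA_TYPES: dict[str, tuple[type, ...]] = {
    "seed": (int,),
    "atlas_mode": (str,),
    "min_samples": (int,),
    "fold_threshold": (int, float),
    "conserved_fraction": (int, float),
    "proximal_bp": (int,),
    "link_window": (int,),
    "alpha": (int, float),
    "expression_min_tpm": (int, float),
    "expression_min_fraction": (int, float),
    "te_fraction": (int, float),
    "peak_fraction": (int, float),
    "n_perm": (int,),
    "cluster_top_n": (int, type(None)),
    "distance_bin_width": (int,),
    "tissue_systems": (dict, type(None)),
    "inputs": (dict,),
    "simulation": (dict,),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(source: str | Path | Mapping[str, Any] | None) -> dict[str, Any]:
    """Merge a user config (YAML path or mapping) over the defaults and
    validate keys and value types against the schema."""
    if source is None:
        user: dict[str, Any] = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config = {**DEFAULT_CONFIG, **user}
    for key, types in _SCHEMA_TYPES.items():
        value = config[key]
        if isinstance(value, bool) or not isinstance(value, types):
            raise ValueError(
                f"config key {key!r}: expected {'/'.join(t.__name__ for t in types)}, "
                f"got {type(value).__name__}"
            )
    return config


def _require_path(inputs: Mapping[str, Any], key: str) -> Path:
    if key not in inputs:
        raise FileNotFoundError(f"missing required input {key!r}")
    path = Path(inputs[key])
    if not path.exists():
        raise FileNotFoundError(f"input {key!r} not found: {path}")
    return path


def _load_inputs(config: Mapping[str, Any], outdir: Path) -> dict[str, Any]:
    inputs = config["inputs"]
    if inputs.get("simulate"):
        sim_kwargs = dict(config["simulation"])
        sim_kwargs.setdefault("seed", config["seed"])
        sim_config = SimulationConfig(**sim_kwargs)
        study = simulate_study(sim_config)
        write_study(study, outdir / "simulated_inputs")
        return {
            "sheet": study.atlas.sheet,
            "per_sample_peaks": study.atlas.per_sample_peaks,
            "counts": study.atlas.counts,
            "tpm": study.tpm,
            "genes": study.genes,
            "chrom_lengths": study.chrom_lengths,
            "tes": study.tes,
            "variants": study.variants,
            "truth": study.truth,
        }
    sheet = SampleSheet.read_tsv(_require_path(inputs, "sample_sheet"))
    peaks_dir = _require_path(inputs, "peaks_dir")
    per_sample = {}
    for sid in sheet.sample_ids:
        bed = peaks_dir / f"{sid}.bed"
        if not bed.exists():
            raise FileNotFoundError(f"peak file for sample {sid!r} not found: {bed}")
        per_sample[sid] = pio.read_bed(bed)
    counts = IntensityMatrix(pio.read_matrix_tsv(_require_path(inputs, "counts")), "counts")
    genes = pio.read_gene_models(_require_path(inputs, "genes"))
    tpm_df = pio.read_matrix_tsv(_require_path(inputs, "tpm"))
    if np.allclose(tpm_df.sum(axis=0), 1e6, rtol=1e-6):
        tpm = IntensityMatrix(tpm_df, "tpm")
    else:  # raw expression counts: TPM-normalize with gene span lengths
        from .quantify import tpm_normalize

        tpm = tpm_normalize(
            IntensityMatrix(tpm_df, "counts"), {g.id: g.end - g.start for g in genes}
        )
    chrom_lengths = pio.read_chrom_lengths(_require_path(inputs, "chrom_lengths"))
    tes = pio.read_repeatmasker_out(_require_path(inputs, "tes")) if "tes" in inputs else []
    variants = pio.read_variants(_require_path(inputs, "variants")) if "variants" in inputs else []
    return {
        "sheet": sheet,
        "per_sample_peaks": per_sample,
        "counts": counts,
        "tpm": tpm,
        "genes": genes,
        "chrom_lengths": chrom_lengths,
        "tes": tes,
        "variants": variants,
        "truth": None,
    }


def _links_to_frame(links):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "peak_id": l.peak_id,
                "gene_id": l.gene_id,
                "distance": l.distance,
                "rho": l.rho,
                "p": l.p,
                "q": l.q,
                "significant": l.significant,
                "sign": l.sign,
            }
            for l in links
        ]
    )


def run_pipeline(
    config: str | Path | Mapping[str, Any] | None,
    outdir: str | Path,
) -> dict[str, Any]:
    """Execute every stage in dependency order and write all artifacts.

    Returns the run report (also written to ``run_report.json``). Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    import pandas as pd

    config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stderr_handler = logging.StreamHandler(sys.stderr)
    log.addHandler(stderr_handler)
    report: dict[str, Any] = {
        "parameters": {
            k: v for k, v in config.items() if k not in ("inputs", "simulation")
        },
        "versions": {"pigatlas": __version__, "numpy": np.__version__},
    }
    log.info("run seed: %s", config["seed"])
    rng = np.random.default_rng(config["seed"])

    # wall times go to the log only, so the report is byte-identical on rerun
    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:
                log.error("stage %s: FAILED: %s", name, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrap

    try:
        data = stage("inputs")(lambda: _load_inputs(config, outdir))

        def build():
            atlas = build_atlas(
                data["per_sample_peaks"],
                data["sheet"],
                mode=config["atlas_mode"],
                min_samples=config["min_samples"],
            )
            atlas.attach_counts(data["counts"])
            return atlas

        atlas = stage("atlas")(build)

        def quantify_stage():
            prox = classify_proximal_distal(
                atlas.peaks, data["genes"], threshold=config["proximal_bp"]
            )
            labels, fractions = annotate_genomic_category(atlas.peaks, data["genes"])
            newick = cluster_samples(atlas.ppkm, top_n=config["cluster_top_n"])
            (outdir / "samples.nwk").write_text(newick + "\n")
            pd.DataFrame(
                {"peak_id": list(labels), "category": list(labels.values()),
                 "location": [prox[p] for p in labels]}
            ).to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
            (outdir / "category_fractions.json").write_text(
                json.dumps(fractions, indent=1, sort_keys=True)
            )
            n_prox = sum(1 for v in prox.values() if v == "proximal")
            return {
                "n_atlas_peaks": len(atlas.peaks),
                "n_proximal": n_prox,
                "n_distal": len(atlas.peaks) - n_prox,
                "category_fractions": fractions,
            }

        report["atlas"] = stage("quantify")(quantify_stage)

        def specificity_stage():
            means = tissue_means(atlas.ppkm, data["sheet"])
            calls = call_specific(means, fold_threshold=config["fold_threshold"])
            rows = [
                {"feature_id": c.feature_id, "level": c.level, "label": c.label,
                 "fold": c.fold, "target_mean": c.target_mean}
                for c in calls
            ]
            grouping = config["tissue_systems"]
            sys_calls = []
            if grouping:
                sys_calls = call_group_specific(
                    means, grouping, fold_threshold=config["fold_threshold"]
                )
                rows += [
                    {"feature_id": c.feature_id, "level": c.level, "label": c.label,
                     "fold": c.fold, "target_mean": c.target_mean}
                    for c in sys_calls
                ]
            pd.DataFrame(rows).to_csv(outdir / "specific_peaks.tsv", sep="\t", index=False)
            conserved = call_conserved(
                atlas.per_tissue_peaks, atlas.peaks, min_fraction=config["conserved_fraction"]
            )
            pd.DataFrame(
                [{"feature_id": c.feature_id, "n_present": c.n_present,
                  "n_total": c.n_total} for c in conserved]
            ).to_csv(outdir / "conserved_peaks.tsv", sep="\t", index=False)
            per_tissue = {t: 0 for t in data["sheet"].tissues}
            for c in calls:
                per_tissue[c.label] += 1
            return {
                "n_specific_peaks": len(calls),
                "per_tissue": per_tissue,
                "n_system_specific": len(sys_calls),
                "n_conserved": len(conserved),
                "calls": calls,
                "conserved": conserved,
            }

        spec_result = stage("specificity")(specificity_stage)
        report["specificity"] = {
            k: v for k, v in spec_result.items() if k not in ("calls", "conserved")
        }

        def links_stage():
            genes_kept = filter_expressed(
                data["tpm"],
                min_tpm=config["expression_min_tpm"],
                min_support=float(config["expression_min_fraction"]),
            )
            tpm_kept = data["tpm"].subset_rows(genes_kept)
            gene_models = [g for g in data["genes"] if g.id in set(genes_kept)]
            shared = [c for c in atlas.ppkm.col_ids if c in set(tpm_kept.col_ids)]
            ppkm_shared = IntensityMatrix(atlas.ppkm.df[shared], "ppkm")
            tpm_shared = IntensityMatrix(tpm_kept.df[shared], tpm_kept.kind)
            pairs = candidate_pairs(atlas.peaks, gene_models, window=config["link_window"])
            links, degenerate = build_link_map(
                ppkm_shared, tpm_shared, pairs, alpha=config["alpha"]
            )
            _links_to_frame(links).to_csv(outdir / "peak_gene_links.tsv", sep="\t", index=False)
            sig = [l for l in links if l.significant]
            summary = link_summary(links, bin_width=config["distance_bin_width"])
            out = {
                "n_genes_tested": len(genes_kept),
                "n_pairs_tested": len(links),
                "n_degenerate_pairs": degenerate,
                "n_significant": len(sig),
                "summary": summary["per_sign"],
            }
            if sig:
                _, assoc_frac, peak_frac = classify_sign_profiles(links)
                out["sign_fractions_associations"] = assoc_frac
                out["sign_fractions_peaks"] = peak_frac
            (outdir / "link_summary.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True)
            )
            return out, links

        link_report, links = stage("links")(links_stage)
        report["links"] = link_report

        def te_stage():
            tes = data["tes"]
            if not tes:
                return {"n_tes": 0}
            accessible = call_accessible_tes(
                tes,
                atlas.per_tissue_peaks,
                te_fraction=config["te_fraction"],
                peak_fraction=config["peak_fraction"],
            )
            sharing = classify_sharing(accessible, data["sheet"].tissues)
            composition = te_class_composition(accessible)
            n_tissues = len(data["sheet"].tissues)
            pd.DataFrame(
                [
                    {
                        "te_id": a.id, "name": a.te.name, "family": a.te.family,
                        "class": a.te.te_class, "chrom": a.te.interval.chrom,
                        "start": a.te.interval.start, "end": a.te.interval.end,
                        "tissues": ",".join(sorted(a.tissues)),
                        "sharing": a.sharing(n_tissues),
                    }
                    for a in accessible
                ]
            ).to_csv(outdir / "accessible_tes.tsv", sep="\t", index=False)
            perm = permutation_enrichment(
                [p.interval for p in atlas.peaks],
                [t.interval for t in tes],
                data["chrom_lengths"],
                n_perm=config["n_perm"],
                seed=rng,
            )
            (outdir / "te_enrichment.json").write_text(
                json.dumps(dataclasses.asdict(perm), indent=1, sort_keys=True)
            )
            return {
                "n_tes": len(tes),
                "n_accessible": len(accessible),
                "sharing": sharing,
                "composition": composition,
                "permutation": {
                    "observed": perm.observed,
                    "p_enrich": perm.p_enrich,
                    "p_deplete": perm.p_deplete,
                    "direction": perm.direction,
                },
            }

        report["te"] = stage("te")(te_stage)

        def variant_stage():
            variants = data["variants"]
            if not variants:
                return {"n_variants": 0}
            annotations = annotate_variants(variants, atlas.peaks)
            prioritize_genes(annotations, links)
            pd.DataFrame(
                [
                    {
                        "id": a.variant.id, "chrom": a.variant.chrom, "pos": a.variant.pos,
                        "trait": a.variant.trait, "p_value": a.variant.p_value,
                        "peak_id": a.peak_id if a.peak_id else "",
                        "linked_genes": ";".join(
                            f"{g}({rho:.3f},q={q:.3g})" for g, rho, q in a.linked_genes
                        ),
                    }
                    for a in annotations
                ]
            ).to_csv(outdir / "variant_annotation.tsv", sep="\t", index=False)
            perm = variant_peak_enrichment(
                variants, atlas.peaks, data["chrom_lengths"],
                n_perm=config["n_perm"], seed=rng,
            )
            (outdir / "variant_enrichment.json").write_text(
                json.dumps(dataclasses.asdict(perm), indent=1, sort_keys=True)
            )
            return {
                "n_variants": len(variants),
                "n_in_peak": sum(1 for a in annotations if a.in_peak),
                "permutation": {
                    "observed": perm.observed,
                    "p_enrich": perm.p_enrich,
                    "p_deplete": perm.p_deplete,
                    "direction": perm.direction,
                },
            }

        report["variants"] = stage("variants")(variant_stage)

        (outdir / "run_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
        return report
    finally:
        log.removeHandler(handler)
        log.removeHandler(stderr_handler)
        handler.close()
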