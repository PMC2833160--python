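"""End-to-end orchestration: read/simulate -> score -> nulls -> topology ->
category stats -> (optional) structure regression, with a run manifest.

The config is a flat mapping (see ``load_config`` for the KEY=VALUE file
format); every value has a CLI flag override. Outputs are plain TSV/JSON so
every denominator in the summary is auditable. Reruns into the same output
directory reuse cached %MinMax profiles when the input checksum and scoring
parameters are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clusters import (
    call_orfeome_clusters,
    classify_terminal_genes,
    clusters_to_frame,
    null_cluster_sets,
    positional_profile,
)
from .minmax import MinMaxProfile, profiles_to_frame, score_orfeome
from .orfeome import (
    compute_usage_table,
    filter_by_length,
    gene_metadata,
    read_orfeome,
    write_orfeome,
    write_usage_table,
)
from .stats import category_enrichment, stratify_expression
from .structure import (
    compare_median_dG,
    flag_5prime_structural_clusters,
    offset_sweep_regression,
    read_deltaG_table,
)
from .synth import (
    SyntheticSpec,
    generate_deltaG,
    generate_orfeome,
    write_annotations,
    write_truth,
)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "window": 18,
    "threshold": -10.0,
    "min_windows": 250,
    "reps": 50,
    "seed": 0,
    "max_pos": 250,
}


def load_config(path: str | Path) -> dict:
    """Flat KEY=VALUE config file; '#' starts a comment."""
    cfg: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected KEY=VALUE): {line!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _annotation_labels(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: annotation TSV needs a gene_id column")
    return df


def run_pipeline(config: dict) -> Path:
    """Execute the full analysis; returns the output directory.

    Config keys: fasta OR synthetic=1 (with optional synthetic_* overrides);
    annotations, dg_table (optional TSVs); window, threshold, min_windows,
    reps, seed, max_pos, outdir.
    """
    cfg = {**DEFAULTS, **{k: v for k, v in config.items() if v is not None}}
    window = int(cfg["window"])
    tau = float(cfg["threshold"])
    min_windows = int(cfg["min_windows"])
    reps = int(cfg["reps"])
    seed = int(cfg["seed"])
    max_pos = int(cfg["max_pos"])
    outdir = Path(cfg.get("outdir", "rarecodon_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "rarecodon_version": __version__,
        "numpy_version": np.__version__,
        "parameters": {
            "window": window, "threshold": tau, "min_windows": min_windows,
            "reps": reps, "seed": seed, "max_pos": max_pos,
        },
        "inputs": {},
    }

    truth = None
    if str(cfg.get("synthetic", "")).lower() in ("1", "true", "yes"):
        sspec = SyntheticSpec(
            n_genes=int(cfg.get("synthetic_n_genes", 2000)),
            q5=float(cfg.get("synthetic_q5", SyntheticSpec.q5)),
            q3=float(cfg.get("synthetic_q3", SyntheticSpec.q3)),
            background_rate=float(
                cfg.get("synthetic_background_rate", SyntheticSpec.background_rate)
            ),
            skew=float(cfg.get("synthetic_skew", SyntheticSpec.skew)),
            window=window,
            tau=tau,
            seed=seed,
        )
        orfeome, truth = generate_orfeome(sspec)
        write_orfeome(orfeome, outdir / "synthetic_orfeome.fasta")
        write_annotations(truth, outdir / "synthetic_annotations.tsv")
        write_truth(truth, outdir / "synthetic_truth.json")
        generate_deltaG(sspec, truth).to_csv(outdir / "synthetic_dg.tsv", sep="\t", index=False)
        manifest["inputs"]["synthetic_spec"] = {
            k: v for k, v in asdict_safe(sspec).items() if not isinstance(v, tuple)
        }
        labels_df = truth.labels
        dg_map = read_deltaG_table(outdir / "synthetic_dg.tsv")
    elif "fasta" in cfg:
        fasta = Path(cfg["fasta"])
        if not fasta.exists():
            raise FileNotFoundError(
                f"input FASTA not found: {fasta} (set fasta= in the config or --fasta)"
            )
        orfeome = read_orfeome(fasta)
        manifest["inputs"]["fasta"] = {"path": str(fasta), "sha256": _sha256(fasta)}
        labels_df = None
        if "annotations" in cfg:
            apath = Path(cfg["annotations"])
            if not apath.exists():
                raise FileNotFoundError(f"annotation TSV not found: {apath}")
            labels_df = _annotation_labels(apath)
            manifest["inputs"]["annotations"] = {"path": str(apath), "sha256": _sha256(apath)}
        dg_map = None
        if "dg_table" in cfg:
            dpath = Path(cfg["dg_table"])
            if not dpath.exists():
                raise FileNotFoundError(f"dG TSV not found: {dpath}")
            dg_map = read_deltaG_table(dpath)
            manifest["inputs"]["dg_table"] = {"path": str(dpath), "sha256": _sha256(dpath)}
    else:
        raise ValueError("config must name an input: fasta=... or synthetic=1")

    # --- orfeome stage ---
    table = compute_usage_table(orfeome)
    write_usage_table(table, outdir / "usage_table.tsv")
    meta = gene_metadata(orfeome, min_windows=min_windows, window=window)
    meta.to_csv(outdir / "gene_metadata.tsv", sep="\t", index=False)
    filtered = filter_by_length(orfeome, min_windows=min_windows, window=window)
    logger.info("retained %d/%d genes", len(filtered), len(orfeome))

    # --- scoring stage (cached) ---
    profile_path = outdir / "minmax_profiles.tsv"
    cache_key = {"window": window, "n_genes": len(filtered),
                 "inputs": manifest["inputs"]}
    cache_tag = hashlib.sha256(json.dumps(cache_key, sort_keys=True, default=str).encode()).hexdigest()
    old_manifest = outdir / "manifest.json"
    profiles = None
    if profile_path.exists() and old_manifest.exists():
        try:
            prev = json.loads(old_manifest.read_text())
            if prev.get("profile_cache_tag") == cache_tag:
                df = pd.read_csv(profile_path, sep="\t")
                profiles = [
                    MinMaxProfile(gid, window, grp["value"].to_numpy())
                    for gid, grp in df.groupby("gene_id", sort=False)
                ]
                logger.info("reusing cached %%MinMax profiles (%d genes)", len(profiles))
        except Exception:  # corrupt cache -> recompute
            profiles = None
    if profiles is None:
        profiles = score_orfeome(filtered, table, window)
        profiles_to_frame(profiles).to_csv(profile_path, sep="\t", index=False)
    manifest["profile_cache_tag"] = cache_tag

    # --- cluster topology ---
    cluster_sets = call_orfeome_clusters(profiles, tau)
    clusters_to_frame(cluster_sets, profiles).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    nulls = null_cluster_sets(filtered, table, reps, seed, tau, window)
    shortest = min((len(cs) for cs in cluster_sets), default=0)
    mp = min(max_pos, shortest)
    summary: dict = {"n_genes_total": len(orfeome), "n_genes_filtered": len(filtered)}
    if mp >= 1 and len(cluster_sets) > 0:
        for orient in ("5prime", "3prime"):
            prof = positional_profile(cluster_sets, orient, mp, nulls)
            prof.to_frame().to_csv(
                outdir / f"positional_profile_{orient}.tsv", sep="\t", index=False
            )
            summary[f"pct_pos1_{orient}"] = float(prof.pct_genes[0])
            summary[f"z_pos1_{orient}"] = float(prof.z[0]) if np.isfinite(prof.z[0]) else None
            if prof.nonterminal_mean is not None:
                summary["pct_nonterminal_mean"] = prof.nonterminal_mean
                summary["pct_nonterminal_sd"] = prof.nonterminal_sd
        counts = classify_terminal_genes(cluster_sets)
        counts.to_csv(outdir / "terminal_counts.tsv", sep="\t", index=False)
        summary["n_genes_any_cluster"] = int(
            sum(1 for cs in cluster_sets if cs.flags.any())
        )

    # --- category statistics ---
    if labels_df is not None and len(cluster_sets) > 0:
        rows = []
        labelled = labels_df.set_index("gene_id")
        flags_first50 = {
            cs.gene_id: bool(cs.flags[:50].any()) for cs in cluster_sets
        }
        flags_last50 = {
            cs.gene_id: bool(cs.flags[::-1][:50].any()) for cs in cluster_sets
        }
        flags_any = {cs.gene_id: bool(cs.flags.any()) for cs in cluster_sets}
        label_cols = [c for c in ("signal", "secreted") if c in labelled.columns]
        for rng_name, fl in (("5prime_50", flags_first50), ("3prime_50", flags_last50), ("all", flags_any)):
            for col in label_cols:
                lab = {g: bool(v) for g, v in labelled[col].items()}
                res = category_enrichment(fl, lab, f"{col} x {rng_name}")
                rows.append({"label": col, "range": rng_name, **res.to_row()})
            if "category" in labelled.columns:
                for cat in sorted(labelled["category"].dropna().unique()):
                    lab = {g: v == cat for g, v in labelled["category"].items()}
                    res = category_enrichment(fl, lab, f"category={cat} x {rng_name}")
                    rows.append({"label": f"category={cat}", "range": rng_name, **res.to_row()})
            expr_cols = [c for c in labelled.columns if c.startswith("cy5_cy3")]
            if expr_cols:
                expr = {g: list(r) for g, r in labelled[expr_cols].iterrows()}
                high, low = stratify_expression(expr)
                for name, members in (("high_expression", high), ("low_expression", low)):
                    lab = {g: g in members for g in labelled.index}
                    res = category_enrichment(fl, lab, f"{name} x {rng_name}")
                    rows.append({"label": name, "range": rng_name, **res.to_row()})
        pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # --- structure regression ---
    if dg_map is not None and len(cluster_sets) > 0:
        struct_flags = flag_5prime_structural_clusters(cluster_sets)
        dg_with = np.array([dg_map[g] for g, f in struct_flags.items() if f and g in dg_map])
        dg_without = np.array([dg_map[g] for g, f in struct_flags.items() if not f and g in dg_map])
        if len(dg_with) and len(dg_without):
            reg = offset_sweep_regression(dg_with, dg_without)
            reg.to_frame().to_csv(outdir / "structure_offsets.tsv", sep="\t", index=False)
            medians = compare_median_dG({"with_cluster": dg_with, "without_cluster": dg_without})
            summary["structure"] = {
                "best_offset": reg.best_offset,
                "best_offset_magnitude": reg.best_offset_magnitude,
                "best_r2": reg.best_r2,
                "median_with": reg.median_with,
                "median_without": reg.median_without,
                "n_with": reg.n_with,
                "n_without": reg.n_without,
            }
            medians.to_csv(outdir / "structure_medians.tsv", sep="\t", index=False)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return outdir


def asdict_safe(obj) -> dict:
    from dataclasses import asdict

    return asdict(obj)
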