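"""End-to-end orchestration: simulate → map → quantify → cluster, and
conserve → scan, with reproducible on-disk outputs.

Every run writes a ``run_metadata.json`` capturing all analysis parameters
actually used (windows in frames, cutoffs in cycles/mm, alpha, seeds), so a
run can be reproduced bit-exactly from its output directory alone.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import enhancer
from .mapping import AnalysisWindows, FilterParams, ResponseMap, make_overlay, map_condition
from .quantify import (ClusterResult, hierarchical_cluster, load_expression_table,
                       expression_rate, pairwise_distances, partition_subregions,
                       response_vector, EXPRESSION_SITES)
from .stacks import ImageStack, load_stack, save_stack
from .stimuli import StimulusSpec
from .synthetic import SyntheticConfig, generate_experiment

log = logging.getLogger("sphmap")


# ---------------------------------------------------------------------------
# simulate


def simulate_experiment(config: SyntheticConfig, conditions: Sequence[StimulusSpec],
                        seed: int, out_dir: str | Path) -> Path:
    """Generate an experiment and write stacks (TIFF+JSON) and truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stacks, truth = generate_experiment(config, conditions, seed)
    for stack in stacks:
        save_stack(stack, out_dir / f"{stack.trial_id}.tif")
    truth.save(out_dir / "truth.json")
    meta = {"seed": seed, "config": _config_dict(config),
            "conditions": [c.to_dict() for c in conditions]}
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out_dir


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["blobs"] = {k: [{"center": list(b.center), "sigma_px": b.sigma_px,
                       "peak_dff": b.peak_dff} for b in v]
                  for k, v in config.blobs.items()}
    return d


# ---------------------------------------------------------------------------
# mapping


def group_stacks(stacks: Sequence[ImageStack]) -> tuple[dict[str, list[ImageStack]], list[ImageStack]]:
    """Split stacks into per-condition groups and the blank group."""
    by_label: dict[str, list[ImageStack]] = {}
    blanks: list[ImageStack] = []
    for s in stacks:
        if s.is_blank:
            blanks.append(s)
        else:
            by_label.setdefault(s.stimulus.label, []).append(s)
    return by_label, blanks


def run_mapping_pipeline(stacks: Sequence[ImageStack] | str | Path,
                         out_dir: str | Path,
                         windows: Optional[AnalysisWindows] = None,
                         filter_params: Optional[FilterParams] = None,
                         alpha: float = 0.01,
                         ap_split_col: Optional[int] = None,
                         dv_split_row: Optional[int] = None,
                         cluster_method: str = "average",
                         ) -> dict[str, ResponseMap]:
    """Map every condition against the blank trials and quantify.

    ``stacks`` is either in-memory stacks or a directory of TIFF+JSON
    trials.  Writes per-condition mean ΔF/F TIFFs and overlay PNGs,
    subregion response vectors and pairwise distances as CSV, the linkage
    tree as JSON, and run metadata.  Raises if any condition lacks blank
    trials to compare against.
    """
    if isinstance(stacks, (str, Path)):
        stacks = [load_stack(p) for p in sorted(Path(stacks).glob("*.tif"))]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = windows or AnalysisWindows.electrical()
    filter_params = filter_params or FilterParams()

    by_label, blanks = group_stacks(stacks)
    if not by_label:
        raise ValueError("no stimulus trials found")
    if not blanks:
        raise ValueError("missing blank trials for condition(s): "
                         + ", ".join(sorted(by_label)))

    first = next(iter(by_label.values()))[0]
    h, w = first.shape[1:]
    ap = ap_split_col if ap_split_col is not None else w // 2
    dv = dv_split_row if dv_split_row is not None else h // 2
    part = partition_subregions((h, w), ap, dv)

    base_sl, stim_sl = windows.frame_windows(first.frame_rate_hz,
                                             first.stimulus_onset_frame,
                                             first.n_frames)
    log.info("analysis windows: baseline frames %s, stimulus frames %s",
             base_sl, stim_sl)
    log.info("band-pass: sigma_hi=%.3g /mm, sigma_lo=%.3g /mm (%.4g mm/px); alpha=%g",
             filter_params.sigma_hi_per_mm, filter_params.sigma_lo_per_mm,
             first.mm_per_px, alpha)

    anatomy = blanks[0].frames.mean(axis=0)
    maps: dict[str, ResponseMap] = {}
    vectors = []
    for label in sorted(by_label):
        rmap, _, _ = map_condition(by_label[label], blanks, windows,
                                   filter_params, alpha=alpha)
        maps[label] = rmap
        tifffile.imwrite(out_dir / f"{label}_mean_dff.tif",
                         rmap.mean_dff.astype(np.float32))
        _write_png(make_overlay(rmap, anatomy), out_dir / f"{label}_overlay.png")
        vectors.append(response_vector(rmap, part, condition=label))
        log.info("condition %s: %.4f of pixels significant at alpha=%g",
                 label, rmap.sig_fraction, alpha)

    vec_df = pd.DataFrame(
        [{"condition": v.condition,
          **{f"mean_dff_{n}": m for n, m in zip(part.names, v.mean_dff)},
          **{f"sig_frac_{n}": f for n, f in zip(part.names, v.sig_fraction)}}
         for v in vectors])
    vec_df.to_csv(out_dir / "response_vectors.csv", index=False)

    cluster: Optional[ClusterResult] = None
    if len(vectors) >= 2:
        dist = pairwise_distances(vectors)
        labels = [v.condition for v in vectors]
        pd.DataFrame(dist, index=labels, columns=labels).to_csv(
            out_dir / "pairwise_distances.csv")
        cluster = hierarchical_cluster(dist, labels, method=cluster_method)
        (out_dir / "dendrogram.json").write_text(json.dumps(
            {"linkage": cluster.linkage.tolist(), "labels": labels,
             "method": cluster_method}, indent=1))

    meta = {
        "windows": asdict(windows),
        "baseline_frames": [base_sl.start, base_sl.stop],
        "stimulus_frames": [stim_sl.start, stim_sl.stop],
        "filter": asdict(filter_params),
        "alpha": alpha,
        "ap_split_col": ap,
        "dv_split_row": dv,
        "cluster_method": cluster_method,
        "n_blank_trials": len(blanks),
        "conditions": {k: len(v) for k, v in by_label.items()},
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return maps


def _write_png(rgb: np.ndarray, path: Path) -> None:
    import matplotlib.pyplot as plt

    plt.imsave(path, np.clip(rgb, 0.0, 1.0))


# ---------------------------------------------------------------------------
# conservation


def run_conservation_pipeline(fasta_path: str | Path, out_dir: str | Path,
                              window_bp: int = 100,
                              identity_threshold: float = 80.0,
                              min_width_bp: int = 100,
                              motif: str = enhancer.TBOX_MOTIF,
                              max_mismatch: int = 1) -> dict:
    """Profile conservation, call elements and scan motifs on an aligned pair.

    Writes profile TSV, elements BED, motif-hit TSV and metadata JSON;
    returns the in-memory results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pair = enhancer.read_alignment_fasta(fasta_path)
    profile = enhancer.sliding_identity(pair, window_bp=window_bp)
    elements = enhancer.call_conserved(profile, identity_threshold=identity_threshold,
                                       min_width_bp=min_width_bp)
    hits = enhancer.motif_scan(pair.ref_ungapped, motif=motif,
                               max_mismatch=max_mismatch)
    enhancer.write_profile_tsv(profile, out_dir / "conservation_profile.tsv")
    enhancer.write_elements_bed(elements, out_dir / "conserved_elements.bed",
                                chrom=pair.ref_name)
    enhancer.write_hits_tsv(hits, out_dir / "motif_hits.tsv")
    meta = {"fasta": str(fasta_path), "window_bp": window_bp,
            "identity_threshold": identity_threshold,
            "min_width_bp": min_width_bp, "motif": motif,
            "max_mismatch": max_mismatch,
            "n_elements": len(elements), "n_hits": len(hits)}
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    log.info("conservation: %d elements, %d motif hits", len(elements), len(hits))
    return {"pair": pair, "profile": profile, "elements": elements, "hits": hits}


# ---------------------------------------------------------------------------
# expression report


def report_expression_rates(table_csv: Optional[str | Path] = None) -> pd.DataFrame:
    """Per-(construct, site) expression rates from a line-summary table.

    Uses the packaged synthetic transcription when no CSV is given.
    Returns a DataFrame with columns construct, site, positive, total,
    percent.
    """
    table = load_expression_table(table_csv)
    rows = []
    for construct in table["construct"].unique():
        for site in EXPRESSION_SITES:
            pos, total, pct = expression_rate(table, construct, site)
            rows.append({"construct": construct, "site": site,
                         "positive": pos, "total": total, "percent": pct})
    return pd.DataFrame(rows)
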