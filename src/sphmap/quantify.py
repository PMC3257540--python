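"""Region-based quantification of response maps and cluster analysis.

Includes ROI time courses in 0.5-s bins, stimulus–response curves
(peak ΔF/F versus pulse count or current), the four-quadrant partition of
the imaged field (dorsal/ventral × anterior/posterior piriform cortex:
APCd, APCv, PPCd, PPCv), per-subregion response vectors, hierarchical
clustering of response patterns with a within/between linkage-distance
comparison, and tabulation of transgene expression rates across transgenic
founders/lines.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .mapping import ResponseMap
from .stacks import ImageStack

SUBREGION_NAMES = ("APCd", "APCv", "PPCd", "PPCv")

EXPRESSION_CONSTRUCTS = ("Tbx5.0gV", "Tbx2.6gV", "Tbx1.0gV", "MCE-gV", "Tbx-spH")
EXPRESSION_SITES = {
    "mitral/tufted": "mitral_tufted",
    "olfactory-pathway": "olfactory_pathway",
    "osn": "osn",
}


# ---------------------------------------------------------------------------
# time courses and stimulus-response curves


def timecourse(stack: ImageStack, roi_mask: np.ndarray, bin_s: float = 0.5,
               ) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F trace of an ROI in fixed time bins.

    The ROI-mean fluorescence is averaged within consecutive bins of
    ``bin_s`` (floored to whole frames; trailing frames that do not fill a
    bin are dropped) and divided by the pre-stimulus ROI baseline mean,
    minus one.  Returns (bin start times in s, ΔF/F per bin).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != stack.frames.shape[1:]:
        raise ValueError("ROI shape does not match the stack")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if bin_s < 1.0 / stack.frame_rate_hz:
        raise ValueError("bin shorter than one frame")
    trace = stack.frames[:, roi_mask].mean(axis=1)
    onset = stack.stimulus_onset_frame
    if onset < 1:
        raise ValueError("no pre-stimulus frames for the baseline")
    baseline = trace[:onset].mean()
    if baseline <= 0:
        raise ValueError("non-positive ROI baseline")
    bin_frames = math.floor(bin_s * stack.frame_rate_hz)
    n_bins = stack.n_frames // bin_frames
    binned = trace[:n_bins * bin_frames].reshape(n_bins, bin_frames).mean(axis=1)
    times = np.arange(n_bins) * bin_frames / stack.frame_rate_hz
    return times, binned / baseline - 1.0


def stimulus_response_curve(trials_by_param: Mapping[float, Sequence[ImageStack]],
                            roi_mask: np.ndarray, bin_s: float = 0.5) -> pd.DataFrame:
    """Peak ΔF/F (mean ± SE over trials) versus a stimulus parameter.

    ``trials_by_param`` keys are the varied stimulus parameter (pulse count
    or current); the per-trial peak is the maximum post-onset binned ΔF/F.
    """
    if len(trials_by_param) < 2:
        raise ValueError("need at least 2 parameter values for a curve")
    rows = []
    for param in sorted(trials_by_param):
        peaks = []
        for stack in trials_by_param[param]:
            times, dff = timecourse(stack, roi_mask, bin_s=bin_s)
            onset_t = stack.stimulus_onset_frame / stack.frame_rate_hz
            post = dff[times >= onset_t]
            if post.size == 0:
                raise ValueError("no post-onset bins")
            peaks.append(post.max())
        peaks = np.asarray(peaks)
        se = peaks.std(ddof=1) / np.sqrt(len(peaks)) if len(peaks) > 1 else 0.0
        rows.append({"param": param, "peak_dff": peaks.mean(),
                     "peak_se": float(se), "n_trials": len(peaks)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subregions


@dataclass
class SubregionPartition:
    """Rectangular four-quadrant labelling of the imaged field.

    One anterior–posterior split (a column index) and one dorsal–ventral
    split (a row index) divide the field into APCd, APCv, PPCd, PPCv.
    Anterior is to the left (columns < split), dorsal is up (rows < split).
    """

    labels: np.ndarray  # int image, 1..4; names[i] is label i+1
    names: tuple = SUBREGION_NAMES
    ap_split_col: int = 0
    dv_split_row: int = 0

    def masks(self) -> dict[str, np.ndarray]:
        return {name: self.labels == i + 1 for i, name in enumerate(self.names)}


def partition_subregions(shape: tuple[int, int], ap_split_col: int,
                         dv_split_row: int) -> SubregionPartition:
    """Quadrant partition of an image of the given (height, width)."""
    h, w = shape
    if not (0 <= ap_split_col <= w) or not (0 <= dv_split_row <= h):
        raise ValueError("split coordinates outside the image")
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    anterior = cols < ap_split_col
    dorsal = rows < dv_split_row
    labels = np.where(anterior & dorsal, 1,
                      np.where(anterior & ~dorsal, 2,
                               np.where(~anterior & dorsal, 3, 4)))
    return SubregionPartition(labels.astype(np.int8), SUBREGION_NAMES,
                              ap_split_col, dv_split_row)


@dataclass
class ResponseVector:
    """Per-subregion summary of one response map.

    Holds the subregion means of ΔF/F and the fraction of significant
    pixels per subregion; ``values`` concatenates them (means first) into
    the 8-element feature vector used for clustering.
    """

    mean_dff: np.ndarray        # length 4
    sig_fraction: np.ndarray    # length 4, in [0, 1] (NaN if region empty)
    condition: str = ""
    replicate: str = ""
    empty_regions: tuple = ()

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.mean_dff, self.sig_fraction])


def response_vector(rmap: ResponseMap, part: SubregionPartition,
                    condition: str = "", replicate: str = "") -> ResponseVector:
    """Subregion means and significant-pixel fractions of a response map.

    Empty subregions are flagged (NaN fraction), never silently zero.
    """
    if part.labels.shape != rmap.sig_mask.shape:
        raise ValueError("partition shape does not match the map")
    means, fracs, empty = [], [], []
    for name, mask in part.masks().items():
        n = int(mask.sum())
        if n == 0:
            means.append(np.nan)
            fracs.append(np.nan)
            empty.append(name)
        else:
            means.append(float(rmap.mean_dff[mask].mean()))
            fracs.append(float(rmap.sig_mask[mask].sum()) / n)
    return ResponseVector(np.asarray(means), np.asarray(fracs),
                          condition=condition, replicate=replicate,
                          empty_regions=tuple(empty))


# ---------------------------------------------------------------------------
# clustering


def _as_matrix(vectors: Sequence) -> np.ndarray:
    arrs = [v.values if isinstance(v, ResponseVector) else np.asarray(v, dtype=np.float64)
            for v in vectors]
    if len(arrs) < 2:
        raise ValueError("need at least 2 vectors")
    lengths = {a.shape for a in arrs}
    if len(lengths) != 1:
        raise ValueError("vectors differ in length")
    return np.stack(arrs)


def pairwise_distances(vectors: Sequence) -> np.ndarray:
    """Euclidean distance matrix between response vectors."""
    x = _as_matrix(vectors)
    if np.isnan(x).any():
        raise ValueError("vectors contain NaN (empty subregion?)")
    return squareform(pdist(x, metric="euclidean"))


@dataclass
class ClusterResult:
    """Agglomerative clustering of response vectors.

    ``linkage`` is the scipy linkage matrix; merge heights are the linkage
    distances.  When class labels are supplied, the within-class and
    between-class pairwise distances are summarised (mean ± SD) and
    compared by a two-sample two-tailed t-test (or a permutation test).
    """

    distances: np.ndarray
    linkage: np.ndarray
    labels: list[str]
    classes: Optional[list[str]] = None
    within_mean: Optional[float] = None
    within_sd: Optional[float] = None
    between_mean: Optional[float] = None
    between_sd: Optional[float] = None
    p_value: Optional[float] = None
    method: str = "average"

    def top_split(self) -> tuple[set, set]:
        """Leaf labels on each side of the dendrogram's final merge."""
        assign = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        a = {l for l, c in zip(self.labels, assign) if c == 1}
        b = {l for l, c in zip(self.labels, assign) if c == 2}
        return a, b


def hierarchical_cluster(distmat: np.ndarray, labels: Sequence[str],
                         classes: Optional[Sequence[str]] = None,
                         method: str = "average",
                         comparison: str = "ttest",
                         n_permutations: int = 10000,
                         rng_seed: int = 0) -> ClusterResult:
    """Agglomerative clustering from a distance matrix (UPGMA by default).

    ``method`` may be 'single', 'complete' or 'average'.  If ``classes``
    gives a class per observation, within- versus between-class pairwise
    distances are compared; ``comparison='permutation'`` replaces the
    t-test with a label-permutation test of the mean difference.
    """
    distmat = np.asarray(distmat, dtype=np.float64)
    n = distmat.shape[0]
    if distmat.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix of size >= 2")
    if not np.allclose(distmat, distmat.T) or np.any(np.diag(distmat) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(labels) != n:
        raise ValueError("labels do not match the matrix")
    if method not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage method: {method}")
    z = hierarchy.linkage(squareform(distmat, checks=False), method=method)
    result = ClusterResult(distances=distmat, linkage=z, labels=list(labels),
                           method=method)
    if classes is not None:
        if len(classes) != n:
            raise ValueError("classes do not match the matrix")
        result.classes = list(classes)
        iu = np.triu_indices(n, k=1)
        same = np.asarray([classes[i] == classes[j] for i, j in zip(*iu)])
        within = distmat[iu][same]
        between = distmat[iu][~same]
        if within.size and between.size:
            result.within_mean = float(within.mean())
            result.within_sd = float(within.std(ddof=1)) if within.size > 1 else 0.0
            result.between_mean = float(between.mean())
            result.between_sd = float(between.std(ddof=1)) if between.size > 1 else 0.0
            if comparison == "ttest":
                result.p_value = float(stats.ttest_ind(within, between).pvalue)
            elif comparison == "permutation":
                rng = np.random.default_rng(rng_seed)
                pooled = np.concatenate([within, between])
                observed = abs(within.mean() - between.mean())
                nw = within.size
                count = 0
                for _ in range(n_permutations):
                    rng.shuffle(pooled)
                    if abs(pooled[:nw].mean() - pooled[nw:].mean()) >= observed:
                        count += 1
                result.p_value = (count + 1) / (n_permutations + 1)
            else:
                raise ValueError(f"unknown comparison: {comparison}")
    return result


# ---------------------------------------------------------------------------
# transgene expression rates


def load_expression_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load a transgenic line summary table (packaged synthetic table by default).

    The packaged table is a synthetic per-line reconstruction: individual
    rows are not the real founders/lines, but the per-construct aggregate
    counts match the published summary.  Columns: ``construct``,
    ``line_id``, ``line_type`` and boolean expression-site flags.
    """
    if path is None:
        ref = resources.files("sphmap.data") / "tbx21_line_summary_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"construct", "line_id"} | set(EXPRESSION_SITES.values())
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("expression table is empty")
    unknown = set(df["construct"]) - set(EXPRESSION_CONSTRUCTS)
    if unknown:
        raise ValueError(f"unknown constructs in table: {sorted(unknown)}")
    for col in EXPRESSION_SITES.values():
        df[col] = df[col].astype(bool)
    return df


def expression_rate(table: pd.DataFrame, construct: str, site: str,
                    ) -> tuple[int, int, int]:
    """(positive, total, percent) for one construct at one expression site.

    ``site`` is a key of :data:`EXPRESSION_SITES` (e.g. 'mitral/tufted').
    Percent is rounded to the nearest integer.
    """
    if construct not in set(table["construct"]):
        raise KeyError(f"construct not in table: {construct}")
    col = EXPRESSION_SITES.get(site, site if site in table.columns else None)
    if col is None or col not in table.columns:
        raise KeyError(f"unknown expression site: {site}")
    sub = table[table["construct"] == construct]
    total = len(sub)
    positive = int(sub[col].sum())
    percent = int(round(100.0 * positive / total))
    return positive, total, percent
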