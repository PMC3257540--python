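"""Comparative-genomics scan of an enhancer locus.

Sliding-window percent-identity profiling of a pairwise alignment,
conserved-element calling at configurable identity/width thresholds
(defaults: 100-bp window, >80% identity, ≥100-bp width), and degenerate
consensus-motif scanning — by default the T-box binding consensus
TCACACCT with up to one substitution, on both strands.

Coordinate conventions
----------------------
Windows are anchored on reference bases: a window is 100 consecutive
reference (ungapped) bases together with whatever the partner shows in the
corresponding alignment columns.  Columns where the reference carries a gap
(insertions in the partner) are skipped entirely; columns where the partner
carries a gap opposite a reference base count as mismatches.  Profile
positions and element coordinates are 1-based on the reference; BED output
converts to 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

TBOX_MOTIF = "TCACACCT"

_ALPHABET = set("ACGTN-")


@dataclass
class AlignmentPair:
    """A pairwise alignment: reference sequence plus aligned partner."""

    ref: str
    partner: str
    ref_name: str = "ref"
    partner_name: str = "partner"
    ref_start: int = 1  # 1-based coordinate of the first reference base

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.partner = self.partner.upper()
        if len(self.ref) != len(self.partner):
            raise ValueError("aligned sequences differ in length")
        bad = (set(self.ref) | set(self.partner)) - _ALPHABET
        if bad:
            raise ValueError(f"unexpected alignment characters: {sorted(bad)}")

    @property
    def ref_ungapped(self) -> str:
        return self.ref.replace("-", "")

    @property
    def ref_length(self) -> int:
        return len(self.ref_ungapped)


@dataclass
class ConservationProfile:
    """Windowed percent identity, anchored at window start reference positions."""

    positions: np.ndarray  # 1-based reference coordinate of each window start
    identity: np.ndarray   # percent, in [0, 100]
    window_bp: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.identity = np.asarray(self.identity, dtype=np.float64)
        if self.positions.shape != self.identity.shape:
            raise ValueError("positions and identity differ in length")
        if np.any(self.identity < 0) or np.any(self.identity > 100):
            raise ValueError("identity outside [0, 100]")


@dataclass(frozen=True)
class ConservedElement:
    """A called conserved interval on the reference (1-based, closed)."""

    start: int
    end: int
    mean_identity: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MotifHit:
    """One degenerate motif match on the ungapped sequence."""

    position: int      # 1-based start on the forward strand
    strand: str        # '+' or '-'
    mismatches: int
    matched: str       # substring as read on the hit strand


# ---------------------------------------------------------------------------
# FASTA I/O


def read_alignment_fasta(path: str | Path) -> AlignmentPair:
    """Read a two-record aligned FASTA; first record is the reference."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, found {len(records)}")
    r, p = records
    if len(r.seq) != len(p.seq):
        raise ValueError(f"{path}: records '{r.id}' and '{p.id}' differ in aligned length")
    return AlignmentPair(str(r.seq), str(p.seq), ref_name=r.id, partner_name=p.id)


def write_alignment_fasta(pair: AlignmentPair, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in ((pair.ref_name, pair.ref), (pair.partner_name, pair.partner)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return path


# ---------------------------------------------------------------------------
# operations


def sliding_identity(pair: AlignmentPair, window_bp: int = 100) -> ConservationProfile:
    """Percent identity in a sliding window of ``window_bp`` reference bases.

    The window slides by one reference base.  Identity is the fraction of
    the window's reference bases whose alignment column matches (partner
    gaps and N count as mismatches), reported at the window's reference
    start position.
    """
    ref = np.frombuffer(pair.ref.encode(), dtype="S1")
    par = np.frombuffer(pair.partner.encode(), dtype="S1")
    ref_cols = ref != b"-"
    n_ref = int(ref_cols.sum())
    if n_ref == 0:
        raise ValueError("alignment has no reference bases")
    if window_bp < 1 or window_bp > n_ref:
        raise ValueError("window longer than the ungapped reference")
    r = ref[ref_cols]
    p = par[ref_cols]
    match = ((r == p) & (r != b"N") & (p != b"N")).astype(np.float64)
    csum = np.concatenate([[0.0], np.cumsum(match)])
    counts = csum[window_bp:] - csum[:-window_bp]
    identity = 100.0 * counts / window_bp
    positions = pair.ref_start + np.arange(n_ref - window_bp + 1)
    return ConservationProfile(positions, identity, window_bp)


def call_conserved(profile: ConservationProfile,
                   identity_threshold: float = 80.0,
                   min_width_bp: int = 100) -> list[ConservedElement]:
    """Call conserved elements from a windowed identity profile.

    Windows with identity strictly greater than the threshold qualify;
    elements are the maximal reference intervals covered by the union of
    qualifying windows, kept if at least ``min_width_bp`` wide.  The
    reported identity is the mean over the qualifying windows that compose
    the element.  The operation is idempotent and its elements are
    disjoint and sorted.
    """
    qual = profile.identity > identity_threshold
    elements: list[ConservedElement] = []
    w = profile.window_bp
    cur_start = cur_end = None
    idents: list[float] = []
    for pos, ident, q in zip(profile.positions, profile.identity, qual):
        if not q:
            continue
        start, end = int(pos), int(pos) + w - 1
        if cur_end is not None and start <= cur_end + 1:
            cur_end = max(cur_end, end)
            idents.append(float(ident))
        else:
            if cur_end is not None:
                elements.append((cur_start, cur_end, idents))
            cur_start, cur_end, idents = start, end, [float(ident)]
    if cur_end is not None:
        elements.append((cur_start, cur_end, idents))
    return [ConservedElement(s, e, float(np.mean(ids)))
            for s, e, ids in elements if e - s + 1 >= min_width_bp]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def motif_scan(sequence: str, motif: str = TBOX_MOTIF, max_mismatch: int = 1,
               both_strands: bool = True) -> list[MotifHit]:
    """Find all approximate occurrences of a consensus motif.

    Every position (on both strands when enabled) whose Hamming distance to
    the motif is at most ``max_mismatch`` is reported; N always counts as a
    mismatch.  Positions are 1-based starts on the forward strand; for a
    '-' hit the matched substring is reported as read on the reverse
    strand.  A motif longer than the sequence yields an empty result.
    """
    sequence = sequence.upper()
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    if "-" in sequence:
        raise ValueError("sequence must be ungapped")
    L, m = len(sequence), len(motif)
    if m == 0:
        raise ValueError("empty motif")
    if m > L:
        return []
    seq = np.frombuffer(sequence.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    hits: list[MotifHit] = []

    def scan(target: str, strand: str) -> None:
        tgt = np.frombuffer(target.encode(), dtype="S1")
        mm = np.sum((windows != tgt) | (windows == b"N"), axis=1)
        for i in np.nonzero(mm <= max_mismatch)[0]:
            sub = sequence[i:i + m]
            hits.append(MotifHit(position=int(i) + 1, strand=strand,
                                 mismatches=int(mm[i]),
                                 matched=sub if strand == "+" else reverse_complement(sub)))

    scan(motif, "+")
    if both_strands:
        scan(reverse_complement(motif), "-")
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def extract_upstream(sequence: str, tss_position: int,
                     upstream_from: int = -3462, upstream_to: int = -3045) -> str:
    """Extract a subsequence by coordinates relative to the TSS.

    Position -1 is the base immediately 5' of the TSS (which sits at
    1-based ``tss_position``); the closed range [upstream_from, upstream_to]
    is returned, of length ``upstream_to - upstream_from + 1``.
    """
    if upstream_to >= 0:
        raise ValueError("coordinates must be upstream (negative)")
    if upstream_from > upstream_to:
        raise ValueError("upstream_from must not exceed upstream_to")
    if not (1 <= tss_position <= len(sequence)):
        raise ValueError("tss_position outside the sequence")
    i0 = tss_position - 1 + upstream_from
    i1 = tss_position - 1 + upstream_to
    if i0 < 0:
        raise ValueError("upstream interval extends beyond the sequence start")
    return sequence[i0:i1 + 1]


# ---------------------------------------------------------------------------
# tabular output


def write_profile_tsv(profile: ConservationProfile, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("position\tidentity_pct\n")
        for pos, ident in zip(profile.positions, profile.identity):
            fh.write(f"{pos}\t{ident:.2f}\n")
    return path


def write_elements_bed(elements: Iterable[ConservedElement], path: str | Path,
                       chrom: str = "ref") -> Path:
    """BED output: 0-based half-open, converted from 1-based closed."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, el in enumerate(elements):
            fh.write(f"{chrom}\t{el.start - 1}\t{el.end}\tconserved_{i + 1}\t"
                     f"{el.mean_identity:.1f}\t+\n")
    return path


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("position\tstrand\tmismatches\tmatched\n")
        for h in hits:
            fh.write(f"{h.position}\t{h.strand}\t{h.mismatches}\t{h.matched}\n")
    return path
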