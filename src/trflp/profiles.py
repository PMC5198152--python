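"""Fingerprint processing: from sized peak tables to a binned T-RF matrix.

The processing chain is fixed:

    size_filter -> denoise -> consolidate_replicates
                -> bin_across_samples -> filter_minor_trfs

Peak *area* (not height) is the abundance measure throughout; relative
abundances are proportions of per-sample total area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Peak:
    """A sized electropherogram peak: fragment size (bp) and fluorescence area."""

    size_bp: float
    area: float

    def __post_init__(self):
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")
        if self.area < 0:
            raise ValueError("area must be non-negative")


@dataclass
class PeakTable:
    """Peaks for one (sample, replicate, enzyme) capillary run."""

    sample_id: str
    replicate: int
    enzyme_name: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class TRFMatrix:
    """Samples x binned-T-RF relative-abundance matrix for one enzyme.

    Rows sum to 1 (or to 0 for a sample with no peaks); bin centers are
    integer bp, strictly increasing.
    """

    enzyme_name: str
    sample_ids: list[str]
    trf_bins: list[int]
    abundance: np.ndarray

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.sample_ids), len(self.trf_bins)):
            raise ValueError("abundance shape does not match sample/bin labels")
        if any(b >= c for b, c in zip(self.trf_bins, self.trf_bins[1:])):
            raise ValueError("bin centers must be strictly increasing")
        rows = self.abundance.sum(axis=1)
        if not np.all((np.abs(rows - 1) < ROW_SUM_TOL) | (rows == 0)):
            raise ValueError("abundance rows must sum to 1 (or 0 for empty samples)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.trf_bins)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, enzyme_name: str) -> "TRFMatrix":
        return cls(enzyme_name, [str(s) for s in df.index],
                   [int(c) for c in df.columns], df.to_numpy(dtype=float))


def size_filter(table: PeakTable, min_bp: float = 50.0, max_bp: float = 500.0) -> PeakTable:
    """Drop peaks outside the sizing window [min_bp, max_bp] (bounds inclusive).

    The defaults mirror the capillary analysis window: fragments below 50 bp
    fall into primer/dye artifacts and those above 500 bp are beyond the
    internal size standard.
    """
    if min_bp >= max_bp:
        raise ValueError("min_bp must be < max_bp")
    kept = [p for p in table.peaks if min_bp <= p.size_bp <= max_bp]
    return replace(table, peaks=kept)


def denoise(table: PeakTable, k: float = 6.0, seed_floor: float = 0.002,
            noise_cap: float = 0.008) -> PeakTable:
    """Remove background noise peaks using a k x SD cutoff on area proportions.

    Areas are first converted to proportions of the run's total area. The
    noise floor is estimated iteratively from below: peaks at or under
    ``seed_floor`` (0.2% of total fluorescence, well below fingerprint
    detection conventions) seed a noise set; its standard deviation about
    zero (root mean squared proportion) sets a cutoff of ``k`` times that
    SD; peaks at or below the cutoff join the noise set and the SD is
    recomputed until the classification is stable. Peaks above the final
    cutoff keep their original areas.

    Only peaks under ``noise_cap`` are noise candidates: the cutoff may
    never claim a peak that the 1% reporting convention would present (the
    0.8% default leaves headroom for noise mass diluting true-peak
    proportions). A table with no peak under ``seed_floor`` has no
    detectable noise floor and passes through unchanged, which makes the
    operation idempotent: every retained peak exceeds the cutoff, so its
    proportion can only grow on a second pass. Raises on all-zero total
    area (no signal to scale against).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not table.peaks:
        raise ValueError("denoise requires at least one peak")
    areas = np.array([p.area for p in table.peaks], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all peak areas are zero: no signal")
    prop = areas / total
    noise = prop <= seed_floor
    if not noise.any():
        return replace(table, peaks=list(table.peaks))
    candidates = prop < noise_cap
    while True:
        cutoff = k * float(np.sqrt(np.mean(prop[noise] ** 2)))
        new_noise = candidates & (prop <= cutoff)
        if np.array_equal(new_noise, noise):
            break
        noise = new_noise
    if noise.all():
        warnings.warn(f"every peak in {table.sample_id!r} classified as noise",
                      stacklevel=2)
    kept = [p for p, is_noise in zip(table.peaks, noise) if not is_noise]
    return replace(table, peaks=kept)


def _cluster(entries, tol: float):
    """Single-linkage 1-D clustering of (size, owner, payload) triples with
    the constraint that no cluster holds two entries from the same owner.

    Chains are formed while consecutive sorted sizes differ by <= tol; a
    chain containing an owner twice (two distinct fragments from one
    replicate or sample) is split recursively at its largest internal gap,
    which separates near-coincident fragment groups such as a 175/176 bp
    pair at their natural boundary.
    """
    entries = sorted(entries, key=lambda e: (e[0], str(e[1])))
    chains: list[list] = []
    for e in entries:
        if chains and e[0] - chains[-1][-1][0] <= tol:
            chains[-1].append(e)
        else:
            chains.append([e])
    out: list[list] = []
    while chains:
        chain = chains.pop()
        owners = [e[1] for e in chain]
        if len(set(owners)) == len(owners) or len(chain) == 1:
            out.append(chain)
            continue
        gaps = [b[0] - a[0] for a, b in zip(chain, chain[1:])]
        cut = int(np.argmax(gaps)) + 1
        chains.append(chain[:cut])
        chains.append(chain[cut:])
    return sorted(out, key=lambda c: c[0][0])


def consolidate_replicates(tables: list[PeakTable], match_tol_bp: float = 1.0) -> PeakTable:
    """Merge replicate runs of one sample into a consensus peak table.

    Peaks are matched across replicates within ``match_tol_bp``; a consensus
    peak is kept iff it appears in a majority (ceil(r/2)) of the r
    replicates. Consensus size and area are means over the replicates that
    contain the peak.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 replicates to consolidate")
    sample_ids = {t.sample_id for t in tables}
    enzymes = {t.enzyme_name for t in tables}
    if len(sample_ids) > 1 or len(enzymes) > 1:
        raise ValueError(f"mixed sample_ids {sample_ids} or enzymes {enzymes}")
    r = len({t.replicate for t in tables})
    if r != len(tables):
        raise ValueError("duplicate replicate numbers")
    quorum = -(-r // 2)  # ceil(r/2)
    entries = [(p.size_bp, t.replicate, p.area) for t in tables for p in t.peaks]
    consensus = []
    for cluster in _cluster(entries, match_tol_bp):
        if len(cluster) >= quorum:
            consensus.append(Peak(size_bp=float(np.mean([e[0] for e in cluster])),
                                  area=float(np.mean([e[2] for e in cluster]))))
    consensus.sort(key=lambda p: p.size_bp)
    return PeakTable(sample_id=tables[0].sample_id, replicate=0,
                     enzyme_name=tables[0].enzyme_name, peaks=consensus)


def bin_across_samples(tables: list[PeakTable], tolerance_bp: float = 2.0) -> TRFMatrix:
    """Align T-RFs across samples into shared integer bins.

    Single-linkage clustering within ``tolerance_bp``, with the constraint
    that two peaks from the same sample never share a bin (they are distinct
    fragments by construction). Bin center = area-weighted mean size rounded
    to the nearest integer; per-sample abundances are areas normalized to
    row sum 1. The 2 bp default matches the sizing drift seen between
    near-identical fragments such as 455/457 or 489/491 variants.
    """
    if tolerance_bp <= 0:
        raise ValueError("tolerance_bp must be positive")
    enzymes = {t.enzyme_name for t in tables}
    if len(enzymes) > 1:
        raise ValueError(f"mixed enzymes: {enzymes}")
    if len({t.sample_id for t in tables}) != len(tables):
        raise ValueError("one consolidated table per sample required")
    sample_ids = [t.sample_id for t in tables]
    entries = [(p.size_bp, t.sample_id, p.area) for t in tables for p in t.peaks]
    centers: list[int] = []
    members: list[list] = []
    for cluster in _cluster(entries, tolerance_bp):
        sizes = np.array([e[0] for e in cluster])
        areas = np.array([e[2] for e in cluster])
        w = areas if areas.sum() > 0 else np.ones_like(areas)
        centers.append(int(round(float(np.average(sizes, weights=w)))))
        members.append(cluster)
    # post-rounding collisions (rare) are merged into one reported bin
    order = np.argsort(centers, kind="stable")
    merged: dict[int, list] = {}
    for i in order:
        merged.setdefault(centers[i], []).extend(members[i])
    bins = sorted(merged)
    abundance = np.zeros((len(sample_ids), len(bins)))
    col = {b: j for j, b in enumerate(bins)}
    for b, cluster in merged.items():
        for size, sid, area in cluster:
            abundance[sample_ids.index(sid), col[b]] += area
    rows = abundance.sum(axis=1, keepdims=True)
    np.divide(abundance, rows, out=abundance, where=rows > 0)
    return TRFMatrix(enzyme_name=tables[0].enzyme_name, sample_ids=sample_ids,
                     trf_bins=bins, abundance=abundance)


def filter_minor_trfs(matrix: TRFMatrix, threshold: float = 0.01):
    """Drop T-RF bins never reaching ``threshold`` relative abundance.

    Mirrors the community-fingerprint reporting rule of presenting only
    T-RFs with at least 1% relative abundance in at least one sample
    (boundary inclusive). Rows are re-normalized; returns
    ``(filtered_matrix, discarded)`` where *discarded* maps sample_id to the
    relative-abundance mass removed from that sample.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    keep = matrix.abundance.max(axis=0) >= threshold
    kept = matrix.abundance[:, keep]
    discarded_mass = matrix.abundance[:, ~keep].sum(axis=1)
    rows = kept.sum(axis=1, keepdims=True)
    kept = np.divide(kept, rows, out=np.zeros_like(kept), where=rows > 0)
    filtered = TRFMatrix(enzyme_name=matrix.enzyme_name, sample_ids=list(matrix.sample_ids),
                         trf_bins=[b for b, k in zip(matrix.trf_bins, keep) if k],
                         abundance=kept)
    discarded = dict(zip(matrix.sample_ids, (float(d) for d in discarded_mass)))
    return filtered, discarded


def process_pipeline(raw_tables: list[PeakTable], *, min_bp: float = 50.0,
                     max_bp: float = 500.0, sd_mult: float = 6.0,
                     replicate_tol_bp: float = 1.0, bin_tol_bp: float = 2.0,
                     min_abundance: float = 0.01):
    """Run the full fixed-order processing chain for one enzyme.

    ``raw_tables`` holds every replicate run of every sample for a single
    enzyme. Returns ``(TRFMatrix, report)``; the report records the
    parameters used and the minor-T-RF mass discarded per sample.
    """
    by_sample: dict[str, list[PeakTable]] = {}
    for t in raw_tables:
        by_sample.setdefault(t.sample_id, []).append(t)
    consolidated = []
    for sid in by_sample:  # insertion order = input sample order
        windowed = [size_filter(t, min_bp, max_bp) for t in by_sample[sid]]
        cleaned = [denoise(t, sd_mult) if t.peaks else t for t in windowed]
        consolidated.append(consolidate_replicates(cleaned, replicate_tol_bp))
    matrix = bin_across_samples(consolidated, bin_tol_bp)
    matrix, discarded = filter_minor_trfs(matrix, min_abundance)
    report = {"min_bp": min_bp, "max_bp": max_bp, "sd_mult": sd_mult,
              "replicate_tol_bp": replicate_tol_bp, "bin_tol_bp": bin_tol_bp,
              "min_abundance": min_abundance, "discarded_mass": discarded}
    return matrix, report
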