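"""Chromatographic fingerprint quality control.

Batch-consistency QC for multi-batch HPLC fingerprints: peak matching against
a common reference pattern, cosine (congruence) similarity on matched
peak-area vectors, and relative-retention-time / relative-peak-area tables
against a designated anchor peak.  This mirrors the pharmacopoeia
fingerprint-similarity workflow in which batches pass when every pairwise
similarity clears a floor (0.98 here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakRecord",
    "PeakTable",
    "Chromatogram",
    "FingerprintReference",
    "AnchorMissingError",
    "match_peaks",
    "build_reference",
    "area_vector",
    "cosine_similarity",
    "similarity_matrix",
    "rrt_rpa_table",
    "integrate_chromatogram",
]


class AnchorMissingError(ValueError):
    """The designated reference (anchor) peak is absent where required."""


@dataclass(frozen=True)
class PeakRecord:
    """One integrated peak: id label, retention time (min), area (mV·s)."""

    peak_id: int
    t_r: float
    area: float

    def __post_init__(self) -> None:
        if self.t_r <= 0:
            raise ValueError(f"t_r must be > 0, got {self.t_r}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")


@dataclass
class PeakTable:
    """An ordered peak list for one batch; t_r strictly increasing, ids unique."""

    batch_id: str
    peaks: list[PeakRecord]

    def __post_init__(self) -> None:
        t = [p.t_r for p in self.peaks]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"batch {self.batch_id}: retention times must be strictly increasing")
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"batch {self.batch_id}: peak ids must be unique")

    def get(self, peak_id: int) -> PeakRecord | None:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        return None

    @property
    def peak_ids(self) -> list[int]:
        return [p.peak_id for p in self.peaks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"peak_id": [p.peak_id for p in self.peaks],
             "t_r_min": [p.t_r for p in self.peaks],
             "area_mvs": [p.area for p in self.peaks]}
        )


@dataclass
class Chromatogram:
    """A sampled intensity trace on a uniform time grid (min)."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass
class FingerprintReference:
    """Common fingerprint pattern: per-peak mean t_r/area plus the anchor id."""

    peaks: PeakTable
    reference_peak_id: int

    def __post_init__(self) -> None:
        if self.peaks.get(self.reference_peak_id) is None:
            raise AnchorMissingError(
                f"anchor peak {self.reference_peak_id} absent from reference pattern"
            )


def _rrt(table: PeakTable, anchor_id: int) -> dict[int, float]:
    anchor = table.get(anchor_id)
    if anchor is None:
        raise AnchorMissingError(
            f"anchor peak {anchor_id} absent from batch {table.batch_id}"
        )
    return {p.peak_id: p.t_r / anchor.t_r for p in table.peaks}


def match_peaks(sample: PeakTable, reference: FingerprintReference,
                rrt_tol: float = 0.02) -> dict[int, int]:
    """Order-preserving nearest-RRT matching of sample peaks to reference peaks.

    Both tables are expressed as relative retention times against the anchor
    peak; candidate pairs within ``rrt_tol`` relative distance are aligned so
    that elution order is preserved (matches never cross), maximizing the
    number of matched peaks and, among those alignments, minimizing the total
    RRT discrepancy.  Each peak is used at most once.  Returns a
    sample-peak-id → reference-peak-id mapping.

    The non-crossing constraint reflects chromatography: peaks keep their
    elution order between runs, so a pure nearest-neighbour assignment that
    swaps two adjacent peaks is always a mis-match.
    """
    if not sample.peaks or not reference.peaks.peaks:
        raise ValueError("both peak tables must be non-empty")
    anchor_id = reference.reference_peak_id
    s_rrt = _rrt(sample, anchor_id)
    r_rrt = _rrt(reference.peaks, anchor_id)
    s_items = [(p.peak_id, s_rrt[p.peak_id]) for p in sample.peaks]
    r_items = [(p.peak_id, r_rrt[p.peak_id]) for p in reference.peaks.peaks]

    ns, nr = len(s_items), len(r_items)
    # dp[i][j]: (matches, -total_cost) for prefixes s[:i], r[:j]; larger is better.
    dp = [[(0, 0.0)] * (nr + 1) for _ in range(ns + 1)]
    move = [[0] * (nr + 1) for _ in range(ns + 1)]  # 1=skip s, 2=skip r, 3=match
    for i in range(1, ns + 1):
        dp[i][0] = (0, 0.0)
        move[i][0] = 1
    for j in range(1, nr + 1):
        dp[0][j] = (0, 0.0)
        move[0][j] = 2
    for i in range(1, ns + 1):
        for j in range(1, nr + 1):
            best, mv = dp[i - 1][j], 1
            if dp[i][j - 1] > best:
                best, mv = dp[i][j - 1], 2
            rel = abs(s_items[i - 1][1] - r_items[j - 1][1]) / r_items[j - 1][1]
            if rel <= rrt_tol:
                cand = (dp[i - 1][j - 1][0] + 1, dp[i - 1][j - 1][1] - rel)
                if cand > best:
                    best, mv = cand, 3
            dp[i][j], move[i][j] = best, mv

    mapping: dict[int, int] = {}
    i, j = ns, nr
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 3:
            mapping[s_items[i - 1][0]] = r_items[j - 1][0]
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    return mapping


def build_reference(tables: list[PeakTable], anchor_peak_id: int,
                    presence_threshold: float = 0.9) -> FingerprintReference:
    """Build the common pattern: per-peak mean t_r and area across batches.

    A peak id is *common* when present in at least ``presence_threshold`` of
    the batches.  Cross-batch correspondence is by peak id (the tables are
    pre-numbered by the upstream matching step).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 batch tables to build a reference pattern")
    missing = [t.batch_id for t in tables if t.get(anchor_peak_id) is None]
    if missing:
        raise AnchorMissingError(
            f"anchor peak {anchor_peak_id} missing from batches: {', '.join(missing)}"
        )
    counts: dict[int, list[PeakRecord]] = {}
    for t in tables:
        for p in t.peaks:
            counts.setdefault(p.peak_id, []).append(p)
    n = len(tables)
    records = [
        PeakRecord(pid,
                   float(np.mean([p.t_r for p in recs])),
                   float(np.mean([p.area for p in recs])))
        for pid, recs in counts.items()
        if len(recs) / n >= presence_threshold
    ]
    records.sort(key=lambda p: p.t_r)
    return FingerprintReference(
        peaks=PeakTable(batch_id="reference", peaks=records),
        reference_peak_id=anchor_peak_id,
    )


def area_vector(table: PeakTable, reference: FingerprintReference,
                rrt_tol: float = 0.02) -> np.ndarray:
    """Matched common-peak area vector, ordered by the reference peak list.

    Reference peaks with no match in the sample contribute 0.
    """
    mapping = match_peaks(table, reference, rrt_tol=rrt_tol)
    inverse = {rid: sid for sid, rid in mapping.items()}
    vec = np.zeros(len(reference.peaks.peaks))
    for i, ref_peak in enumerate(reference.peaks.peaks):
        sid = inverse.get(ref_peak.peak_id)
        if sid is not None:
            vec[i] = table.get(sid).area
    return vec


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Congruence coefficient Σaᵢbᵢ/√(Σaᵢ²·Σbᵢ²); scale-invariant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def similarity_matrix(tables: list[PeakTable], reference: FingerprintReference,
                      rrt_tol: float = 0.02) -> pd.DataFrame:
    """Pairwise batch similarities plus an each-vs-reference row/column 'R'.

    Symmetric, unit diagonal; entries are cosine similarities of matched
    common-peak area vectors.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 batch tables")
    labels = [t.batch_id for t in tables] + ["R"]
    vectors = [area_vector(t, reference, rrt_tol=rrt_tol) for t in tables]
    vectors.append(np.array([p.area for p in reference.peaks.peaks]))
    size = len(vectors)
    mat = np.ones((size, size))
    for i in range(size):
        for j in range(i + 1, size):
            mat[i, j] = mat[j, i] = cosine_similarity(vectors[i], vectors[j])
    return pd.DataFrame(mat, index=labels, columns=labels)


def rrt_rpa_table(sample: PeakTable, anchor_peak_id: int) -> pd.DataFrame:
    """Per-peak relative retention time and relative peak area vs the anchor.

    RRT = t_r / t_r(anchor), RPA = area / area(anchor); both rounded to three
    decimals as conventionally reported.
    """
    anchor = sample.get(anchor_peak_id)
    if anchor is None:
        raise AnchorMissingError(
            f"anchor peak {anchor_peak_id} absent from batch {sample.batch_id}"
        )
    if anchor.area <= 0:
        raise ValueError(f"anchor peak {anchor_peak_id} has zero area")
    return pd.DataFrame(
        {"peak_id": [p.peak_id for p in sample.peaks],
         "t_r_min": [round(p.t_r, 3) for p in sample.peaks],
         "rrt": [round(p.t_r / anchor.t_r, 3) for p in sample.peaks],
         "area_mvs": [round(p.area, 3) for p in sample.peaks],
         "rpa": [round(p.area / anchor.area, 3) for p in sample.peaks]}
    )


def integrate_chromatogram(chrom: Chromatogram,
                           peak_windows: list[tuple[float, float]],
                           time_unit_scale: float = 60.0) -> PeakTable:
    """Trapezoidal peak integration over explicit time windows.

    ``time_unit_scale`` converts the grid's time unit into the reported area
    unit (60 turns a min grid into mV·s areas).  The apex time within each
    window is reported as t_r; peaks are numbered 1..len(windows) in window
    order.
    """
    records = []
    order = np.argsort([w[0] for w in peak_windows])
    for new_id, idx in enumerate(order, start=1):
        lo, hi = peak_windows[idx]
        mask = (chrom.times >= lo) & (chrom.times <= hi)
        if not np.any(mask):
            raise ValueError(f"window ({lo}, {hi}) contains no samples")
        t = chrom.times[mask]
        y = chrom.intensities[mask]
        area = float(np.trapezoid(y, t)) * time_unit_scale
        apex = float(t[np.argmax(y)])
        records.append(PeakRecord(new_id, apex, max(area, 0.0)))
    return PeakTable(batch_id="integrated", peaks=records)
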